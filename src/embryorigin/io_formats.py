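"""Readers and writers for every tabular format the pipeline touches.

All pipeline inputs are plain text: HTSeq-count style TSV count tables
(two-column per-sample files or a wide matrix with a header), microarray
raw-intensity TSVs with a two-column probe-to-gene map, qPCR CT tables as
CSV, and embryo tally TSVs.  Parsing is strict: every failure names the
offending line or field, counts must be raw non-negative integers, and
HTSeq summary rows (``__no_feature`` etc.) are stripped on read because
they are not genes and would corrupt presence calling.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("embryo", "sperm", "oocyte")
FERTILITY_GROUPS = ("high", "low", "none")
QPCR_GROUPS = ("high", "low", "treated", "control")


class FormatError(ValueError):
    """A malformed input table; the message names the offending line/field."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing sample.

    ``fertility_group`` only applies to embryo samples (the sire's fertility
    status); gamete samples carry ``"none"``.
    """

    sample_id: str
    tissue: str
    fertility_group: str = "none"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r}"
            )
        if self.fertility_group not in FERTILITY_GROUPS:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown fertility group "
                f"{self.fertility_group!r}"
            )
        if self.tissue != "embryo" and self.fertility_group != "none":
            raise FormatError(
                f"sample {self.sample_id!r}: fertility_group must be 'none' "
                f"for tissue {self.tissue!r}"
            )
        if self.replicate < 1:
            raise FormatError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


@dataclass
class GeneCountTable:
    """Gene-by-sample matrix of raw (unnormalized) integer read counts.

    ``counts`` is indexed by gene_id with one column per sample, in the
    order of ``samples``.  Counts must be non-negative integers; the
    presence thresholds downstream are defined on raw read counts, so
    normalized input is invalid here.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample identifiers in sample sheet")
        if list(self.counts.columns) != ids:
            raise FormatError(
                "count columns do not match sample sheet: "
                f"{list(self.counts.columns)} vs {ids}"
            )
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene_id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers (raw read counts)")
        if (arr < 0).any():
            bad = self.counts.index[(arr < 0).any(axis=1)][0]
            raise FormatError(f"negative count for gene {bad!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneCountTable":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        return GeneCountTable(self.counts[[s.sample_id for s in keep]].copy(), keep)


@dataclass
class IntensityTable:
    """Probe-level raw microarray intensities plus a probe-to-gene map.

    The map may be many-to-one (several probes per gene); a probe mapped to
    several genes is rejected as ambiguous.  Probes without a mapping are
    retained and flagged in ``unmapped``.
    """

    intensities: pd.DataFrame  # probe_id x array columns, float >= 0
    probe_to_gene: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        arr = self.intensities.to_numpy(dtype=float)
        if (arr < 0).any():
            bad = self.intensities.index[(arr < 0).any(axis=1)][0]
            raise FormatError(f"negative intensity for probe {bad!r}")
        missing = set(self.probe_to_gene) - set(self.intensities.index)
        if missing:
            raise FormatError(
                f"probe {sorted(missing)[0]!r} in map but not in intensity table"
            )

    def gene_intensities(self) -> dict[str, np.ndarray]:
        """Replicate-averaged intensity per probe, grouped by gene.

        Returns gene_id -> vector of per-probe mean intensities (one entry
        per probe mapped to the gene).
        """
        means = self.intensities.mean(axis=1)
        out: dict[str, list[float]] = {}
        for probe, gene in self.probe_to_gene.items():
            out.setdefault(gene, []).append(float(means.loc[probe]))
        return {g: np.asarray(v) for g, v in out.items()}


@dataclass
class QpcrTable:
    """Long-format qPCR CT records: (replicate, group, gene_id, ct).

    Missing CTs (empty cells in the source CSV) are preserved as NaN; the
    quantification cutoff (CT > 33) is applied downstream, not at parse
    time.
    """

    records: pd.DataFrame

    COLUMNS = ("replicate", "group", "gene_id", "ct")

    def __post_init__(self) -> None:
        if list(self.records.columns) != list(self.COLUMNS):
            raise FormatError(
                f"qPCR table columns must be {self.COLUMNS}, "
                f"got {list(self.records.columns)}"
            )
        bad_group = ~self.records["group"].isin(QPCR_GROUPS)
        if bad_group.any():
            val = self.records.loc[bad_group, "group"].iloc[0]
            raise FormatError(f"unknown qPCR group label {val!r}")
        ct = self.records["ct"]
        finite = ct.dropna()
        if not np.isfinite(finite).all() or (finite <= 0).any():
            raise FormatError("CT values must be finite and > 0 when present")

    def ct(self, replicate: int, group: str, gene_id: str) -> float:
        """Look up one CT value; NaN if absent or recorded as missing."""
        m = self.records[
            (self.records["replicate"] == replicate)
            & (self.records["group"] == group)
            & (self.records["gene_id"] == gene_id)
        ]
        if m.empty:
            return float("nan")
        return float(m["ct"].iloc[0])


@dataclass(frozen=True)
class EmbryoTally:
    """Per-replicate, per-arm embryo development tallies."""

    replicate: int
    arm: str
    n_oocytes: int
    n_cleaved: int
    n_blastocyst: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_blastocyst <= self.n_cleaved <= self.n_oocytes):
            raise FormatError(
                f"tally replicate {self.replicate} arm {self.arm!r}: need "
                f"0 <= blastocysts ({self.n_blastocyst}) <= cleaved "
                f"({self.n_cleaved}) <= oocytes ({self.n_oocytes})"
            )


def _as_text(stream: IO[str] | str) -> IO[str]:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def _parse_int_count(token: str, lineno: int, gene: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise FormatError(
            f"line {lineno}: non-integer count {token!r} for gene {gene!r}"
        ) from None
    if value < 0:
        raise FormatError(f"line {lineno}: negative count for gene {gene!r}")
    return value


def read_count_table(
    stream: IO[str] | str, sample_sheet: Sequence[SampleMeta]
) -> GeneCountTable:
    """Parse an HTSeq-count style count table.

    Two dialects are accepted: the native two-column (gene_id, count) output
    for a single sample, and a wide TSV whose header row names the samples
    of ``sample_sheet``.  HTSeq summary rows (identifiers beginning with
    ``__``) are dropped and their removal logged.
    """
    samples = list(sample_sheet)
    fh = _as_text(stream)
    lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("empty count table")

    first = lines[0].split("\t")
    sample_ids = [s.sample_id for s in samples]
    if first[1:] == sample_ids and len(first) >= 2:
        body, offset = lines[1:], 2
    elif len(first) == 2 and len(samples) == 1 and first[1] != sample_ids[0]:
        body, offset = lines, 1
    else:
        raise FormatError(
            "header does not match sample sheet and table is not "
            "two-column single-sample"
        )

    genes: list[str] = []
    rows: list[list[int]] = []
    n_summary = 0
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise FormatError(
                f"line {i + offset}: expected {len(samples) + 1} fields, "
                f"got {len(fields)}"
            )
        gene = fields[0]
        if gene.startswith("__"):
            n_summary += 1
            continue
        genes.append(gene)
        rows.append(
            [_parse_int_count(tok, i + offset, gene) for tok in fields[1:]]
        )
    if n_summary:
        logger.info("dropped %d HTSeq summary rows", n_summary)
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                      columns=sample_ids, dtype=np.int64)
    return GeneCountTable(df, samples)


def write_count_table(table: GeneCountTable, stream: IO[str]) -> None:
    """Write the wide TSV dialect (header row of sample ids)."""
    stream.write("gene_id\t" + "\t".join(table.counts.columns) + "\n")
    for gene, row in table.counts.iterrows():
        stream.write(gene + "\t" + "\t".join(str(v) for v in row) + "\n")


def combine_count_tables(tables: Iterable[GeneCountTable]) -> GeneCountTable:
    """Outer-join single-sample tables on gene_id; absent genes count 0."""
    tables = list(tables)
    samples = [s for t in tables for s in t.samples]
    df = pd.concat([t.counts for t in tables], axis=1).fillna(0).astype(np.int64)
    return GeneCountTable(df, samples)


def read_sample_sheet(stream: IO[str] | str) -> list[SampleMeta]:
    """TSV with header: sample_id, tissue, fertility_group, replicate."""
    df = pd.read_csv(_as_text(stream), sep="\t", dtype=str)
    expected = ["sample_id", "tissue", "fertility_group", "replicate"]
    if list(df.columns) != expected:
        raise FormatError(f"sample sheet columns must be {expected}")
    return [
        SampleMeta(r.sample_id, r.tissue, r.fertility_group, int(r.replicate))
        for r in df.itertuples()
    ]


def read_intensity_table(
    stream: IO[str] | str, map_stream: IO[str] | str
) -> IntensityTable:
    """Parse a probe-intensity TSV (header row of array ids) and a
    two-column probe-to-gene map."""
    df = pd.read_csv(_as_text(stream), sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity: {exc}") from None

    mapping: dict[str, str] = {}
    for i, line in enumerate(_as_text(map_stream), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"probe map line {i}: expected 2 fields")
        probe, gene = fields
        if probe in mapping and mapping[probe] != gene:
            raise FormatError(
                f"probe map line {i}: probe {probe!r} mapped to several genes"
            )
        mapping[probe] = gene
    unmapped = set(df.index) - set(mapping)
    if unmapped:
        logger.info("%d probes have no gene mapping (retained, flagged)",
                    len(unmapped))
    return IntensityTable(df, mapping, unmapped)


def read_qpcr_table(stream: IO[str] | str) -> QpcrTable:
    """Parse a qPCR CSV with columns replicate, group, gene_id, ct.

    Empty CT cells are preserved as missing (NaN).
    """
    df = pd.read_csv(_as_text(stream), dtype={"gene_id": str, "group": str})
    expected = list(QpcrTable.COLUMNS)
    if list(df.columns) != expected:
        raise FormatError(f"qPCR table columns must be {expected}")
    df["replicate"] = df["replicate"].astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    return QpcrTable(df)


def write_qpcr_table(table: QpcrTable, stream: IO[str]) -> None:
    table.records.to_csv(stream, index=False)


def read_tally_table(stream: IO[str] | str) -> list[EmbryoTally]:
    """Parse an embryo tally TSV: replicate, arm, oocytes, cleaved,
    blastocysts (header required)."""
    lines = [ln.rstrip("\n") for ln in _as_text(stream) if ln.strip()]
    if not lines:
        logger.warning("empty tally table")
        return []
    header = lines[0].split("\t")
    expected = ["replicate", "arm", "n_oocytes", "n_cleaved", "n_blastocyst"]
    if header != expected:
        raise FormatError(f"tally header must be {expected}, got {header}")
    out = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"tally line {i}: expected 5 fields")
        try:
            out.append(
                EmbryoTally(int(fields[0]), fields[1], int(fields[2]),
                            int(fields[3]), int(fields[4]))
            )
        except ValueError as exc:
            raise FormatError(f"tally line {i}: {exc}") from None
    return out


def write_tally_table(tallies: Sequence[EmbryoTally], stream: IO[str]) -> None:
    stream.write("replicate\tarm\tn_oocytes\tn_cleaved\tn_blastocyst\n")
    for t in tallies:
        stream.write(
            f"{t.replicate}\t{t.arm}\t{t.n_oocytes}\t{t.n_cleaved}\t"
            f"{t.n_blastocyst}\n"
        )


def write_tsv(df: pd.DataFrame, stream: IO[str], index: bool = False) -> None:
    """Write a result table (origin assignments, DE results, validation
    summaries) as TSV with the DataFrame's column order."""
    df.to_csv(stream, sep="\t", index=index)
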