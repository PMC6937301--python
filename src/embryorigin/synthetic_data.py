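"""Synthetic pipeline inputs with planted ground truth.

The generated study mirrors the experimental design the pipeline targets:
six 2-4 cell embryo RNA-seq samples (three from high-fertility sires,
three from low), two sperm samples (one sire per fertility group), two
oocyte RNA-seq replicates, one probe-level microarray oocyte reference,
qPCR CT plates, and paired treated/control embryo tallies.

Every gene carries a planted origin label; genes whose origin includes a
gamete get expressed-level negative-binomial counts in that gamete's
dataset and background-level counts otherwise.  "Not expressed" is
simulated as NB with a small background mean (default 0.5) rather than a
structural zero, so the presence thresholds are actually exercised.
Provisional genes are planted as expressed in exactly one of the two
oocyte references (coin flip), mirroring the disagreement that triggers
the provisional rule.  All genes are embryo-expressed; planted DE genes
split the embryo group means symmetrically around ``nb_mean`` by
``de_log2fc``.

Counts follow NB(mean m, dispersion phi) with variance m + phi m^2;
phi = 0 degenerates to Poisson and background mean 0 to structural zeros,
which together give a noise-free configuration that downstream stages
must recover exactly.  A single global seed drives one named random
stream per generator, so adding a generator does not perturb the others.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    EmbryoTally,
    GeneCountTable,
    IntensityTable,
    QpcrTable,
    SampleMeta,
)

_STREAMS = {
    "origin": 1, "embryo": 2, "sperm": 3, "oocyte_rnaseq": 4,
    "oocyte_array": 5, "qpcr": 6, "tally": 7,
}

ORIGIN_LABELS = (
    "sperm_and_oocyte", "oocyte_only", "sperm_only", "embryo_only",
    "provisional",
)

#: Default origin mixture, proportioned after the published four-category
#: breakdown of embryo-expressed RNAs, with a 10% provisional slice.
DEFAULT_ORIGIN_PROPORTIONS = {
    "sperm_and_oocyte": 0.377,
    "oocyte_only": 0.363,
    "sperm_only": 0.066,
    "embryo_only": 0.094,
    "provisional": 0.100,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study-design defaults.

    nb_mean / nb_dispersion parameterize the expressed-level count
    distribution (variance = m + phi m^2); background_mean is the
    not-expressed level.  de_log2fc is the planted high-vs-low effect for
    the de_fraction of genes flagged DE.  rates maps arm -> (cleavage
    probability, blastocyst-given-cleaved probability).
    """

    seed: int = 0
    n_genes: int = 10_000
    origin_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_PROPORTIONS)
    )
    nb_mean: float = 100.0
    nb_dispersion: float = 0.2
    background_mean: float = 0.5
    n_embryo_reps_per_group: int = 3
    n_sperm_samples: int = 2
    n_oocyte_rnaseq_reps: int = 2
    n_array_reps: int = 3
    de_fraction: float = 0.05
    de_log2fc: float = 3.0
    array_expressed_mean: float = 500.0
    array_background_mean: float = 10.0
    array_log_sd: float = 0.2
    qpcr_noise_sd: float = 0.25
    n_qpcr_replicates: int = 3
    reference_gene: str = "ACTB"
    rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (0.80, 0.35),
            "treated": (0.80, 0.43),
        }
    )
    n_tally_replicates: int = 3
    n_oocytes_per_arm: int = 150

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.origin_proportions) != set(ORIGIN_LABELS):
            raise ValueError(
                f"origin_proportions must have keys {ORIGIN_LABELS}"
            )
        total = sum(self.origin_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin_proportions sum to {total}, not 1")
        if self.nb_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("nb_mean must be > 0 and nb_dispersion >= 0")
        if self.background_mean < 0 or self.array_background_mean < 0:
            raise ValueError("background means must be >= 0")
        if self.array_expressed_mean <= 0 or self.qpcr_noise_sd < 0:
            raise ValueError("array_expressed_mean > 0, qpcr_noise_sd >= 0")
        for arm, (c, b) in self.rates.items():
            if not (0 <= c <= 1 and 0 <= b <= 1):
                raise ValueError(f"rates for arm {arm!r} must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "rates" in d:
            d["rates"] = {k: tuple(v) for k, v in d["rates"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, stream: IO[str] | str) -> "SimulationConfig":
        import yaml

        fh = io.StringIO(stream) if isinstance(stream, str) else stream
        return cls.from_dict(yaml.safe_load(fh) or {})

    def rng(self, stream: str) -> np.random.Generator:
        """Named per-generator random stream derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence((int(self.seed), _STREAMS[stream]))
        )


@dataclass
class TruthTable:
    """Planted ground truth: per gene, its origin label, DE status and
    effect, and the planted per-dataset expression flags used to audit
    recovery failures."""

    table: pd.DataFrame  # gene_id, true_origin, is_de, true_log2fc,
    #                      sperm_expressed, oocyte1_expressed, oocyte2_expressed

    def origin_of(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["true_origin"]))

    def write(self, stream: IO[str]) -> None:
        self.table.to_csv(stream, sep="\t", index=False)


@dataclass
class SyntheticDataset:
    truth: TruthTable
    embryo: GeneCountTable
    sperm: GeneCountTable
    oocyte_rnaseq: GeneCountTable
    oocyte_array: IntensityTable


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float, size
) -> np.ndarray:
    """NB(mean, dispersion) counts; Poisson at dispersion 0, zeros at mean 0."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _count_matrix(
    rng: np.random.Generator,
    means: np.ndarray,  # genes x samples expected counts
    dispersion: float,
) -> np.ndarray:
    out = np.empty(means.shape, dtype=np.int64)
    for j in range(means.shape[1]):
        col = means[:, j]
        out[:, j] = 0
        for m in np.unique(col):
            mask = col == m
            out[mask, j] = _nb_draw(rng, float(m), dispersion, int(mask.sum()))
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full multi-platform study with planted truth.

    Identical config (including seed) yields bit-identical tables.
    """
    n = config.n_genes
    genes = np.array([f"G{i:06d}" for i in range(1, n + 1)])

    rng_o = config.rng("origin")
    labels = np.array(ORIGIN_LABELS)
    probs = np.array([config.origin_proportions[l] for l in labels])
    origin = rng_o.choice(labels, size=n, p=probs / probs.sum())

    in_sperm = np.isin(origin, ("sperm_and_oocyte", "sperm_only"))
    in_oocyte = np.isin(origin, ("sperm_and_oocyte", "oocyte_only"))
    oocyte1 = in_oocyte.copy()
    oocyte2 = in_oocyte.copy()
    prov = origin == "provisional"
    # provisional: expressed in exactly one oocyte reference, coin flip which
    which_ref = rng_o.random(n) < 0.5
    oocyte1[prov] = which_ref[prov]
    oocyte2[prov] = ~which_ref[prov]
    # provisional genes may or may not be sperm-expressed; it cannot rescue
    # them from the provisional label either way
    in_sperm = in_sperm | (prov & (rng_o.random(n) < 0.5))

    is_de = rng_o.random(n) < config.de_fraction
    sign = np.where(rng_o.random(n) < 0.5, 1.0, -1.0)
    true_log2fc = np.where(is_de, sign * config.de_log2fc, 0.0)

    # embryo: all genes expressed; DE genes split the two group means
    # symmetrically so the planted high/low ratio is 2^true_log2fc
    mean_hi = config.nb_mean * 2.0 ** (true_log2fc / 2.0)
    mean_lo = config.nb_mean * 2.0 ** (-true_log2fc / 2.0)
    k = config.n_embryo_reps_per_group
    embryo_means = np.column_stack([mean_hi] * k + [mean_lo] * k)
    embryo_counts = _count_matrix(
        config.rng("embryo"), embryo_means, config.nb_dispersion
    )
    embryo_samples = [
        SampleMeta(f"embryo_high_{i+1}", "embryo", "high", i + 1)
        for i in range(k)
    ] + [
        SampleMeta(f"embryo_low_{i+1}", "embryo", "low", i + 1)
        for i in range(k)
    ]
    embryo = GeneCountTable(
        pd.DataFrame(embryo_counts,
                     index=pd.Index(genes, name="gene_id"),
                     columns=[s.sample_id for s in embryo_samples]),
        embryo_samples,
    )

    def gamete_table(flag: np.ndarray, n_samples: int, prefix: str,
                     stream: str) -> GeneCountTable:
        means = np.where(flag, config.nb_mean, config.background_mean)
        mat = _count_matrix(
            config.rng(stream),
            np.column_stack([means] * n_samples),
            config.nb_dispersion,
        )
        samples = [
            SampleMeta(f"{prefix}_{i+1}", prefix.split("_")[0], "none", i + 1)
            for i in range(n_samples)
        ]
        return GeneCountTable(
            pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                         columns=[s.sample_id for s in samples]),
            samples,
        )

    sperm = gamete_table(in_sperm, config.n_sperm_samples, "sperm", "sperm")
    oocyte_rnaseq = gamete_table(
        oocyte2, config.n_oocyte_rnaseq_reps, "oocyte_rnaseq", "oocyte_rnaseq"
    )

    # microarray reference: one probe per gene, log-normal intensities
    rng_a = config.rng("oocyte_array")
    arr_mean = np.where(oocyte1, config.array_expressed_mean,
                        config.array_background_mean)
    noise = np.exp(
        rng_a.normal(0.0, config.array_log_sd, size=(n, config.n_array_reps))
    )
    intens = arr_mean[:, None] * noise
    probes = np.array([f"P_{g}" for g in genes])
    array = IntensityTable(
        pd.DataFrame(intens, index=pd.Index(probes, name="probe_id"),
                     columns=[f"array_{j+1}" for j in range(config.n_array_reps)]),
        {p: g for p, g in zip(probes, genes)},
    )

    truth = TruthTable(pd.DataFrame({
        "gene_id": genes,
        "true_origin": origin,
        "is_de": is_de,
        "true_log2fc": true_log2fc,
        "sperm_expressed": in_sperm,
        "oocyte1_expressed": oocyte1,
        "oocyte2_expressed": oocyte2,
    }))
    return SyntheticDataset(truth, embryo, sperm, oocyte_rnaseq, array)


def simulate_qpcr(
    truth: TruthTable,
    genes: Sequence[str],
    config: SimulationConfig,
    folds: Mapping[str, float] | None = None,
    case_group: str = "high",
    control_group: str = "low",
) -> QpcrTable:
    """CT plates for the given genes plus the reference gene.

    The planted fold f enters as ddCT = -log2(f) in expectation: the
    case-condition target CT is lowered by log2(f) relative to control,
    and independent Gaussian noise of sd ``qpcr_noise_sd`` cycles is added
    to every CT.  The reference gene is appended automatically with a
    planted fold of 1.
    """
    if folds is None:
        t = truth.table.set_index("gene_id")
        missing = [g for g in genes if g not in t.index]
        if missing:
            raise KeyError(f"genes not in truth table: {missing}")
        folds = {
            g: float(2.0 ** t.loc[g, "true_log2fc"]) for g in genes
        }
    rng = config.rng("qpcr")
    ref_ct, target_ct = 15.0, 25.0
    rows = []
    all_genes = list(genes) + [config.reference_gene]
    for rep in range(1, config.n_qpcr_replicates + 1):
        for gene in all_genes:
            f = folds.get(gene, 1.0) if gene != config.reference_gene else 1.0
            base = ref_ct if gene == config.reference_gene else target_ct
            ct_case = base - np.log2(f) + rng.normal(0, config.qpcr_noise_sd)
            ct_control = base + rng.normal(0, config.qpcr_noise_sd)
            rows.append((rep, case_group, gene, ct_case))
            rows.append((rep, control_group, gene, ct_control))
    return QpcrTable(
        pd.DataFrame(rows, columns=["replicate", "group", "gene_id", "ct"])
    )


def simulate_tallies(config: SimulationConfig) -> list[EmbryoTally]:
    """Paired per-replicate arms of binomial cleavage/blastocyst tallies."""
    rng = config.rng("tally")
    out = []
    for rep in range(1, config.n_tally_replicates + 1):
        for arm in sorted(config.rates):
            cleave_p, blast_p = config.rates[arm]
            n_cleaved = int(rng.binomial(config.n_oocytes_per_arm, cleave_p))
            n_blast = int(rng.binomial(n_cleaved, blast_p))
            out.append(
                EmbryoTally(rep, arm, config.n_oocytes_per_arm,
                            n_cleaved, n_blast)
            )
    return out


def audit_label_disagreements(
    dataset: SyntheticDataset,
    assignments: pd.DataFrame,
    thresholds=None,
) -> pd.DataFrame:
    """Explain every planted-vs-recovered origin label disagreement.

    A disagreement is *explained* when at least one per-dataset presence
    call differs from the planted expression flag for that gene — i.e.
    sampling noise carried counts across the threshold boundary.  Any
    unexplained disagreement would indicate a classifier logic error, not
    noise.  Returns one row per disagreeing gene with the planted and
    recovered labels, the flipped datasets, and an ``explained`` flag.
    """
    from .expression_calls import (
        Status,
        ThresholdConfig,
        call_count_table,
        call_intensity_table,
    )

    thresholds = thresholds or ThresholdConfig()
    truth = dataset.truth.table.set_index("gene_id")
    recovered = dict(zip(assignments["gene_id"], assignments["label"]))

    calls = {
        "sperm": call_count_table(dataset.sperm, thresholds),
        "oocyte2": call_count_table(dataset.oocyte_rnaseq, thresholds),
        "oocyte1": call_intensity_table(dataset.oocyte_array, thresholds),
    }
    planted_cols = {
        "sperm": "sperm_expressed",
        "oocyte1": "oocyte1_expressed",
        "oocyte2": "oocyte2_expressed",
    }
    rows = []
    for gene, row in truth.iterrows():
        rec = recovered.get(gene, "<not_classified>")
        if rec == row["true_origin"]:
            continue
        flipped = [
            name
            for name, col in planted_cols.items()
            if (calls[name].get(gene, Status.NOT_MEASURED) == Status.EXPRESSED)
            != bool(row[col])
        ]
        if gene not in recovered:
            flipped.append("embryo")  # fell below the embryo presence call
        rows.append(
            (gene, row["true_origin"], rec, ",".join(flipped), bool(flipped))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "planted", "recovered", "flipped_datasets",
                 "explained"],
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["rates"] = {k: list(v) for k, v in d["rates"].items()}
    return d
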