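"""Synthetic round-spermatid sequencing data with known ground truth.

Emulates the downstream structure of a paired mRNA-seq / miRNA-seq study of
three genotypes (wild type, knock-out, knock-in): negative-binomial count
matrices with planted differentially expressed features, two independent
miRNA sequencing batches each containing the wild type plus exactly one
mutant genotype, three partially overlapping miRNA-target databases seeded
with planted true pairs, and random gene-set collections for enrichment
testing.  Every artifact is a deterministic function of the seed, and the
planted truth is returned alongside so downstream stages can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import CountMatrix
from .enrichment import GeneSetCollection
from .targets import TargetDB, normalize_mirna_name

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_target_dbs",
    "simulate_gene_sets",
    "simulate_experiment",
    "write_truth",
    "read_truth",
]

MUTANT_CONTRASTS = ("KO", "KI")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the real study's design where it states one (six mRNA-seq
    replicates per genotype, five miRNA-seq replicates, ~15,000 expressed
    genes, ~1,000 miRNAs, two miRNA batches) and conventional RNA-seq
    simulation values elsewhere (log-normal baseline means around 100 counts,
    NB dispersion 0.05, planted |LFC| of 2, 3% of features perturbed).
    """

    n_genes: int = 15_000
    n_mirnas: int = 1_000
    n_per_group: int = 6
    genotypes: tuple[str, ...] = ("WT", "KO", "KI")
    frac_de: float = 0.03
    lfc_magnitude: float = 2.0
    dispersion: float = 0.05
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.5
    n_batches_mirna: int = 2
    seed: int = 0
    #: fractions of planted-DE features perturbed in KO only, KI only, or both
    de_split: tuple[float, float, float] = (0.25, 0.25, 0.5)
    #: per-sample library-size factors are drawn uniformly from this range
    size_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_per_group", "n_batches_mirna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if abs(sum(self.de_split) - 1.0) > 1e-9:
            raise ValueError("de_split must sum to 1")


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic run.

    ``de_features`` maps a feature id (as it appears in the count matrix) to
    its true log2 fold change per contrast, e.g. ``{"KO": 2.0, "KI": -2.0}``;
    features absent from the map are null in every contrast.  ``true_pairs``
    holds planted (miRNA, gene) target pairs with normalized miRNA names.
    """

    de_features: dict[str, dict[str, float]] = field(default_factory=dict)
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    batch_of_sample: dict[str, str] = field(default_factory=dict)
    mirnas: list[str] = field(default_factory=list)  # normalized ids
    genes: list[str] = field(default_factory=list)

    def merged_with(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            de_features={**self.de_features, **other.de_features},
            true_pairs=self.true_pairs | other.true_pairs,
            batch_of_sample={**self.batch_of_sample, **other.batch_of_sample},
            mirnas=self.mirnas or other.mirnas,
            genes=self.genes or other.genes,
        )


# ---------------------------------------------------------------------------
# feature naming
# ---------------------------------------------------------------------------


def _gene_names(n: int) -> list[str]:
    return [f"Gene{i:05d}" for i in range(n)]


def _mirna_canonical(n: int, rng: np.random.Generator) -> list[str]:
    # ~20% of miRNAs are -3p species; the strand suffix is part of their
    # identity, while -5p is the implied default and may be dropped
    is_3p = rng.random(n) < 0.2
    return [f"miR{100 + i}" + ("-3p" if flag else "") for i, flag in zip(range(n), is_3p)]


def _decorate_mirna(canonical: str, rng: np.random.Generator) -> str:
    """Render a canonical miRNA id the way annotation pipelines print it."""
    name = canonical
    if not name.endswith("-3p") and rng.random() < 0.5:
        name = name + "-5p"
    # miRBase style inserts a dash after the stem
    if rng.random() < 0.5:
        name = "miR-" + name[len("miR") :]
    if rng.random() < 0.5:
        name = "mmu-" + name
    return name


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _plan_de(
    features: list[str], cfg: SimConfig, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    n_de = int(round(cfg.frac_de * len(features)))
    if n_de == 0:
        return {}
    chosen = rng.choice(len(features), size=n_de, replace=False)
    n_ko = int(round(cfg.de_split[0] * n_de))
    n_ki = int(round(cfg.de_split[1] * n_de))
    de: dict[str, dict[str, float]] = {}
    for rank, idx in enumerate(chosen):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * cfg.lfc_magnitude
        if rank < n_ko:
            contrasts = ("KO",)
        elif rank < n_ko + n_ki:
            contrasts = ("KI",)
        else:
            contrasts = ("KO", "KI")  # mutants behave similarly: same planted LFC
        de[features[idx]] = {c: lfc for c in contrasts if c in cfg.genotypes}
    return {f: v for f, v in de.items() if v}


def _assign_batches(cfg: SimConfig, assay: str) -> dict[str, str]:
    """Batch per (genotype, replicate) cell; sample names are built later.

    mRNA runs in a single batch.  miRNA replicates follow the confounded
    two-batch design: each mutant genotype is sequenced entirely in its own
    batch (KI in batch1, KO in batch2, further mutants round-robin) and the
    wild-type replicates are split across batches, so no batch ever contains
    two mutant genotypes and mutants can only be contrasted against WT.
    """
    batches: dict[str, str] = {}
    mutants = [g for g in cfg.genotypes if g != "WT"]
    for genotype in cfg.genotypes:
        for rep in range(cfg.n_per_group):
            sample = f"{assay}_{genotype}_{rep + 1}"
            if assay != "miRNA" or cfg.n_batches_mirna == 1:
                batches[sample] = "batch1"
            elif genotype == "WT":
                batches[sample] = f"batch{rep % cfg.n_batches_mirna + 1}"
            elif genotype == "KI":
                batches[sample] = "batch1"
            elif genotype == "KO":
                batches[sample] = f"batch{min(2, cfg.n_batches_mirna)}"
            else:
                k = mutants.index(genotype) % cfg.n_batches_mirna
                batches[sample] = f"batch{k + 1}"
    return batches


def simulate_counts(cfg: SimConfig, assay: str = "mRNA") -> tuple[CountMatrix, SimTruth]:
    """Draw one NB count matrix for the given assay with planted DE.

    Counts for feature i in sample j are NB with mean
    base_i * 2^(planted LFC of genotype_j) * s_j and dispersion
    ``cfg.dispersion`` (variance mu + alpha mu^2); s_j is the sample's
    library-size factor.  Planted DE therefore shifts group means by exactly
    2^LFC in expectation.
    """
    if assay == "mRNA":
        rng = np.random.default_rng([cfg.seed, 0])
        n_features = cfg.n_genes
        canonical = _gene_names(n_features)
        matrix_names = list(canonical)
    elif assay == "miRNA":
        rng = np.random.default_rng([cfg.seed, 1])
        n_features = cfg.n_mirnas
        canonical = _mirna_canonical(n_features, rng)
        matrix_names = [_decorate_mirna(c, rng) for c in canonical]
    else:
        raise ValueError(f"unknown assay {assay!r}; expected 'mRNA' or 'miRNA'")

    base_mu = rng.lognormal(cfg.mean_log_mu, cfg.sd_log_mu, size=n_features)
    de = _plan_de(matrix_names, cfg, rng)

    batch_map = _assign_batches(cfg, assay)
    samples = list(batch_map)
    genotype_of = {s: s.split("_")[1] for s in samples}
    lo, hi = cfg.size_factor_range
    size_factors = rng.uniform(lo, hi, size=len(samples))

    lfc_matrix = np.zeros((n_features, len(samples)))
    name_to_row = {name: i for i, name in enumerate(matrix_names)}
    for feat, per_contrast in de.items():
        for j, s in enumerate(samples):
            lfc_matrix[name_to_row[feat], j] = per_contrast.get(genotype_of[s], 0.0)

    mu = base_mu[:, None] * (2.0**lfc_matrix) * size_factors[None, :]
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(
        pd.DataFrame(counts, index=matrix_names, columns=samples),
        pd.DataFrame(
            {
                "genotype": [genotype_of[s] for s in samples],
                "assay": assay,
                "batch": [batch_map[s] for s in samples],
            },
            index=pd.Index(samples, name="sample"),
        ),
    )
    truth = SimTruth(
        de_features=de,
        batch_of_sample=batch_map,
        mirnas=[normalize_mirna_name(n) for n in matrix_names] if assay == "miRNA" else [],
        genes=matrix_names if assay == "mRNA" else [],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# target databases
# ---------------------------------------------------------------------------

_DB_NAMES = ("TargetScanSim", "TarBaseSim", "MiRDBSim")


def simulate_target_dbs(
    cfg: SimConfig,
    truth: SimTruth,
    overlap_frac: float = 0.1,
    noise_pairs_per_db: int = 500,
) -> list[TargetDB]:
    """Three target databases seeded with the planted true pairs plus decoys.

    Every true pair appears in all three databases.  Each database also gets
    ``noise_pairs_per_db`` decoy pairs, of which a fraction ``overlap_frac``
    is shared by all three (so the tri-database intersection contains the
    true pairs plus only those shared decoys); the remaining decoys are
    disjoint across databases by construction.
    """
    if not truth.mirnas or not truth.genes:
        raise ValueError("truth must carry the simulated miRNA and gene name lists")
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 2])
    n_shared = int(round(overlap_frac * noise_pairs_per_db))
    n_needed = n_shared + 3 * (noise_pairs_per_db - n_shared)

    decoys: list[tuple[str, str]] = []
    seen = set(truth.true_pairs)
    while len(decoys) < n_needed:
        m = truth.mirnas[rng.integers(len(truth.mirnas))]
        g = truth.genes[rng.integers(len(truth.genes))]
        if (m, g) not in seen:
            seen.add((m, g))
            decoys.append((m, g))
    shared = decoys[:n_shared]
    rest = decoys[n_shared:]
    per_db = noise_pairs_per_db - n_shared
    dbs = []
    for k, name in enumerate(_DB_NAMES):
        own = rest[k * per_db : (k + 1) * per_db]
        dbs.append(TargetDB(name=name, pairs=frozenset(truth.true_pairs) | set(shared) | set(own)))
    return dbs


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(
    universe: list[str], n_sets: int, set_size: int, seed: int = 0
) -> GeneSetCollection:
    """Random gene sets sampled without replacement from the universe."""
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    rng = np.random.default_rng(seed)
    sets = {
        f"set{i + 1:02d}": sorted(rng.choice(universe, size=set_size, replace=False))
        for i in range(n_sets)
    }
    return GeneSetCollection(sets=sets, universe=list(universe))


# ---------------------------------------------------------------------------
# whole-experiment convenience
# ---------------------------------------------------------------------------


def simulate_experiment(
    cfg_mrna: SimConfig,
    cfg_mirna: SimConfig | None = None,
    n_true_pairs: int = 150,
    frac_pairs_de: float = 0.7,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Generate linked mRNA and miRNA matrices and plant target pairs.

    A fraction ``frac_pairs_de`` of the planted pairs joins a miRNA and a gene
    that are both differentially expressed in a common contrast (so a correct
    pipeline can recover them); the rest pair arbitrary features and should be
    filtered out by the DE conditions.
    """
    if cfg_mirna is None:
        cfg_mirna = replace(cfg_mrna, n_per_group=5)
    mrna_cm, mrna_truth = simulate_counts(cfg_mrna, "mRNA")
    mirna_cm, mirna_truth = simulate_counts(cfg_mirna, "miRNA")
    truth = mrna_truth.merged_with(mirna_truth)

    rng = np.random.default_rng([cfg_mrna.seed, 3])
    raw_to_norm = {raw: norm for raw, norm in zip(mirna_cm.features, truth.mirnas)}
    de_mirnas: dict[str, list[str]] = {c: [] for c in MUTANT_CONTRASTS}
    de_genes: dict[str, list[str]] = {c: [] for c in MUTANT_CONTRASTS}
    for feat, per_contrast in mirna_truth.de_features.items():
        for c in per_contrast:
            de_mirnas[c].append(raw_to_norm[feat])
    for feat, per_contrast in mrna_truth.de_features.items():
        for c in per_contrast:
            de_genes[c].append(feat)

    pairs: set[tuple[str, str]] = set()
    n_linked = int(round(frac_pairs_de * n_true_pairs))
    usable = [c for c in MUTANT_CONTRASTS if de_mirnas[c] and de_genes[c]]
    attempts = 0
    while len(pairs) < n_linked and usable and attempts < 50 * n_true_pairs:
        c = usable[rng.integers(len(usable))]
        m = de_mirnas[c][rng.integers(len(de_mirnas[c]))]
        g = de_genes[c][rng.integers(len(de_genes[c]))]
        pairs.add((m, g))
        attempts += 1
    while len(pairs) < n_true_pairs and attempts < 100 * n_true_pairs:
        m = truth.mirnas[rng.integers(len(truth.mirnas))]
        g = truth.genes[rng.integers(len(truth.genes))]
        pairs.add((m, g))
        attempts += 1
    truth.true_pairs = pairs
    return mrna_cm, mirna_cm, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, path) -> None:
    doc = {
        "de_features": truth.de_features,
        "true_pairs": sorted(map(list, truth.true_pairs)),
        "batch_of_sample": truth.batch_of_sample,
        "mirnas": truth.mirnas,
        "genes": truth.genes,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return SimTruth(
        de_features=doc["de_features"],
        true_pairs={tuple(p) for p in doc["true_pairs"]},
        batch_of_sample=doc["batch_of_sample"],
        mirnas=doc["mirnas"],
        genes=doc["genes"],
    )
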