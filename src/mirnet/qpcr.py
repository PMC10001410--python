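"""Relative quantification of qPCR validation data (comparative Ct method).

Each sample contributes a target Ct and a reference Ct (18S rRNA for mRNA
assays, U6 snRNA for miRNA assays).  Delta Ct = target - reference per
sample; delta-delta Ct = mean delta Ct of the test group minus that of the
control group; fold change = 2^(-ddCt).  The spread across replicates is
summarized as the SEM of per-replicate folds, each computed against the mean
control delta Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "DdctResult",
    "ddct_fold_change",
    "read_qpcr_tsv",
    "fold_change_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One replicate's paired target/reference cycle thresholds."""

    sample: str
    group: str
    target_ct: float
    reference_ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("target_ct", "reference_ct"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass(frozen=True)
class DdctResult:
    """Fold change of the test group relative to the control group."""

    fold: float
    log2_fold: float
    sem: float
    n_test: int
    n_control: int


def ddct_fold_change(
    test: list[QpcrMeasurement], control: list[QpcrMeasurement]
) -> DdctResult:
    """Comparative-Ct fold change, 2^(-ddCt), with replicate SEM.

    Invariant under any additive shift applied to both target and reference
    Ct of a sample (only the difference enters), and reciprocal when the two
    groups are swapped.  SEM is NaN with a single test replicate.
    """
    if not test or not control:
        raise ValueError("need at least one replicate per group")
    d_test = np.array([m.delta_ct for m in test])
    d_control = np.array([m.delta_ct for m in control])
    ddct = d_test.mean() - d_control.mean()
    fold = 2.0**-ddct
    per_replicate = 2.0 ** -(d_test - d_control.mean())
    sem = (
        float(per_replicate.std(ddof=1) / math.sqrt(len(per_replicate)))
        if len(per_replicate) > 1
        else float("nan")
    )
    return DdctResult(
        fold=float(fold),
        log2_fold=float(-ddct),
        sem=sem,
        n_test=len(test),
        n_control=len(control),
    )


# ---------------------------------------------------------------------------
# I/O — TSV schema: sample, group, gene, ct, is_reference
# ---------------------------------------------------------------------------


def read_qpcr_tsv(path) -> dict[str, list[QpcrMeasurement]]:
    """Pair target and reference wells per (gene, sample).

    Returns measurements grouped by target gene.  Each sample must carry
    exactly one reference well (shared by all target genes of that sample);
    a missing reference is an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "gene", "ct", "is_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"qPCR TSV must have columns {sorted(required)}")
    df["is_reference"] = df["is_reference"].astype(bool)
    refs = df[df["is_reference"]]
    ref_ct = {}
    for sample, sub in refs.groupby("sample"):
        if len(sub) != 1:
            raise ValueError(f"sample {sample!r} has {len(sub)} reference wells, expected 1")
        ref_ct[sample] = float(sub["ct"].iloc[0])
    out: dict[str, list[QpcrMeasurement]] = {}
    for idx, (_, row) in enumerate(df[~df["is_reference"]].iterrows()):
        sample = row["sample"]
        if sample not in ref_ct:
            raise ValueError(f"sample {sample!r} has no reference well")
        out.setdefault(str(row["gene"]), []).append(
            QpcrMeasurement(
                sample=str(sample),
                group=str(row["group"]),
                target_ct=float(row["ct"]),
                reference_ct=ref_ct[sample],
                replicate=idx + 1,
            )
        )
    return out


def fold_change_table(
    measurements: dict[str, list[QpcrMeasurement]],
    control_group: str = "WT",
) -> pd.DataFrame:
    """Fold change per gene per non-control group versus the control group."""
    rows = []
    for gene in sorted(measurements):
        per_group: dict[str, list[QpcrMeasurement]] = {}
        for m in measurements[gene]:
            per_group.setdefault(m.group, []).append(m)
        if control_group not in per_group:
            raise ValueError(f"gene {gene!r} has no {control_group!r} replicates")
        for group in sorted(per_group):
            if group == control_group:
                continue
            res = ddct_fold_change(per_group[group], per_group[control_group])
            rows.append(
                {
                    "gene": gene,
                    "comparison": f"{group}-vs-{control_group}",
                    "fold": res.fold,
                    "log2_fold": res.log2_fold,
                    "sem": res.sem,
                    "n_test": res.n_test,
                    "n_control": res.n_control,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "comparison", "fold", "log2_fold", "sem", "n_test", "n_control"],
    )
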