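"""Compilation of supported miRNA-mRNA target pairs.

A pair is *supported* in a contrast when (1) it is present in all three
target databases, (2) the miRNA is differentially expressed in that contrast
and (3) the target mRNA is differentially expressed in the matching mRNA
contrast.  Pairs are not required to change in opposite directions (indirect
effects are kept) and the many-to-many structure is preserved: one miRNA may
target many mRNAs and one mRNA may be targeted by many miRNAs.  The
*canonical* flag records whether the two log2 fold changes have opposite
signs (repression-consistent).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TargetDB",
    "SupportedPair",
    "normalize_mirna_name",
    "intersect_databases",
    "filter_supported_pairs",
    "read_target_db_tsv",
    "write_target_dbs_tsv",
    "read_target_dbs_tsv",
    "write_supported_pairs_tsv",
]

# species prefix (mmu-, hsa-, ...) then a miR/let stem with optional dash
_MIRNA_RE = re.compile(r"^(?:[a-z]{3,4}-)?(mir|let)-?(.*)$", re.IGNORECASE)


def normalize_mirna_name(raw: str) -> str:
    """Canonicalize a miRNA identifier across annotation dialects.

    Strips a species prefix (``mmu-miR-26a`` -> ``miR26a``), drops the
    implied-default ``-5p`` strand suffix while preserving the distinguishing
    ``-3p``, normalizes the stem to ``miR``/``let`` and removes the dash after
    it.  Idempotent: applying it twice changes nothing.
    """
    name = raw.strip()
    if not name:
        raise ValueError("empty miRNA id")
    m = _MIRNA_RE.match(name)
    if m is None:
        return name
    stem = "miR" if m.group(1).lower() == "mir" else "let"
    rest = m.group(2)
    if rest.lower().endswith("-5p"):
        rest = rest[:-3]
    return stem + rest


@dataclass(frozen=True)
class TargetDB:
    """A named set of (miRNA, target gene) pairs."""

    name: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError(f"database {self.name!r} contains an empty id")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SupportedPair:
    """A tri-database pair whose both members are DE in one contrast."""

    mirna: str
    gene: str
    contrast: str
    mirna_lfc: float
    gene_lfc: float
    canonical: bool


def intersect_databases(dbs: list[TargetDB]) -> set[tuple[str, str]]:
    """Pairs present in all three databases (ids must be pre-normalized)."""
    if len(dbs) != 3:
        raise ValueError(f"expected exactly 3 databases, got {len(dbs)}")
    names = {db.name for db in dbs}
    if len(names) != 3:
        raise ValueError("database names must be distinct")
    return set(dbs[0].pairs) & set(dbs[1].pairs) & set(dbs[2].pairs)


def filter_supported_pairs(
    intersection: set[tuple[str, str]],
    de_mirna,
    de_mrna,
    contrast: str,
) -> list[SupportedPair]:
    """Reduce the tri-database intersection to pairs with both members DE.

    ``de_mirna`` and ``de_mrna`` are DEResult objects for the same contrast
    (miRNA and mRNA assays respectively).  miRNA ids are normalized on both
    sides; gene symbols are matched case-insensitively after trimming.
    Database pairs whose miRNA or gene never appears in the corresponding
    result are reported via a warning rather than silently dropped.
    """
    for res in (de_mirna, de_mrna):
        if res.spec.name != contrast:
            raise ValueError(
                f"contrast {contrast!r} not matched by DE result {res.spec.name!r}"
            )

    def _index(result, normalize: bool):
        table: dict[str, tuple[bool, float]] = {}
        for feat, row in result.table.iterrows():
            key = normalize_mirna_name(feat) if normalize else str(feat).strip().casefold()
            table[key] = (bool(row["is_de"]), float(row["lfc"]))
        return table

    mirna_idx = _index(de_mirna, normalize=True)
    gene_idx = _index(de_mrna, normalize=False)

    from .network import classify_canonical

    supported: list[SupportedPair] = []
    unmatched: set[str] = set()
    for mirna_raw, gene_raw in sorted(intersection):
        mirna = normalize_mirna_name(mirna_raw)
        gene = gene_raw.strip()
        m_entry = mirna_idx.get(mirna)
        g_entry = gene_idx.get(gene.casefold())
        if m_entry is None:
            unmatched.add(mirna)
            continue
        if g_entry is None:
            unmatched.add(gene)
            continue
        (m_de, m_lfc), (g_de, g_lfc) = m_entry, g_entry
        if m_de and g_de:
            supported.append(
                SupportedPair(
                    mirna=mirna,
                    gene=gene,
                    contrast=contrast,
                    mirna_lfc=m_lfc,
                    gene_lfc=g_lfc,
                    canonical=classify_canonical(m_lfc, g_lfc),
                )
            )
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} database identifiers had no feature in the DE results "
            f"(e.g. {sorted(unmatched)[:5]})",
            stacklevel=2,
        )
    return supported


# ---------------------------------------------------------------------------
# I/O — TSV schema: mirna, target, db (one row per pair)
# ---------------------------------------------------------------------------


def read_target_db_tsv(path, name: str | None = None) -> TargetDB:
    """Read one database from a (mirna, target[, db]) TSV; normalizes miRNA ids."""
    df = pd.read_csv(path, sep="\t")
    if name is None:
        if "db" not in df.columns or df["db"].nunique() != 1:
            raise ValueError("provide a name or a single-valued 'db' column")
        name = str(df["db"].iloc[0])
    pairs = frozenset(
        (normalize_mirna_name(str(m)), str(g).strip()) for m, g in zip(df["mirna"], df["target"])
    )
    return TargetDB(name=name, pairs=pairs)


def write_target_dbs_tsv(dbs: list[TargetDB], path) -> None:
    rows = [
        {"mirna": m, "target": g, "db": db.name}
        for db in dbs
        for m, g in sorted(db.pairs)
    ]
    pd.DataFrame(rows, columns=["mirna", "target", "db"]).to_csv(path, sep="\t", index=False)


def read_target_dbs_tsv(path) -> list[TargetDB]:
    df = pd.read_csv(path, sep="\t")
    dbs = []
    for name, sub in df.groupby("db", sort=True):
        pairs = frozenset(
            (normalize_mirna_name(str(m)), str(g).strip())
            for m, g in zip(sub["mirna"], sub["target"])
        )
        dbs.append(TargetDB(name=str(name), pairs=pairs))
    return dbs


def write_supported_pairs_tsv(pairs: list[SupportedPair], path) -> None:
    rows = [
        {
            "mirna": p.mirna,
            "gene": p.gene,
            "contrast": p.contrast,
            "mirna_lfc": p.mirna_lfc,
            "gene_lfc": p.gene_lfc,
            "canonical": p.canonical,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["mirna", "gene", "contrast", "mirna_lfc", "gene_lfc", "canonical"]
    ).to_csv(path, sep="\t", index=False)
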