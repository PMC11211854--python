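"""Ligand-receptor pair databases and the raw count container.

Candidate ligand-receptor pairs come from CellChatDB-style tables in which a
ligand or receptor may be a heteromeric complex (several gene subunits joined
by a delimiter, e.g. ``ITGAV_ITGB8``).  Complex expression is the per-spot sum
of the subunit counts; pairs whose ligand or receptor is expressed in too few
spots are filtered out before model fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LRPair",
    "CountMatrix",
    "parse_lr_database",
    "collapse_complex",
    "filter_pairs",
]


@dataclass(frozen=True)
class LRPair:
    """A candidate ligand-receptor pair.

    ``ligand_genes`` and ``receptor_genes`` are ordered tuples of gene
    symbols; a length > 1 denotes a heteromeric complex whose expression is
    the sum over subunits.
    """

    pair_id: str
    ligand_genes: tuple[str, ...]
    receptor_genes: tuple[str, ...]
    pathway: str | None = None

    def __post_init__(self) -> None:
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError("ligand_genes and receptor_genes must be non-empty")

    @property
    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        return frozenset(self.ligand_genes), frozenset(self.receptor_genes)


@dataclass
class CountMatrix:
    """Raw spot x gene UMI counts with per-spot sequencing depths.

    ``depths`` are the *full-matrix* row sums N_i (total UMI per spot), which
    act as exposure offsets in the Poisson marginals Pois(N_i e^mu).  They are
    computed once from the complete matrix, so they upper-bound the row sum of
    any gene subset.
    """

    spot_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray  # (n_spots, n_genes) non-negative integers
    depths: np.ndarray  # (n_spots,) positive integers
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integral UMI counts")
        self.counts = self.counts.astype(np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if np.any(self.depths <= 0):
            raise ValueError("depths must be positive")
        if len(self.spot_ids) != self.counts.shape[0]:
            raise ValueError("spot_ids length mismatch")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length mismatch")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_counts(cls, spot_ids, gene_ids, counts) -> "CountMatrix":
        """Build with depths set to full-matrix row sums (zero-depth spots
        get depth 1 so the Poisson offset stays positive)."""
        counts = np.asarray(counts)
        depths = np.maximum(counts.sum(axis=1), 1)
        return cls(list(spot_ids), list(gene_ids), counts, depths)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    def gene_column(self, gene: str) -> np.ndarray:
        return self.counts[:, self._gene_index[gene]]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index


class LRFormatError(ValueError):
    """Raised when a ligand-receptor table lacks a required column."""


_DIALECT_COLUMNS = {
    "cellchat_tsv": ("ligand", "receptor"),
    "two_column_tsv": ("ligand", "receptor"),
}


def parse_lr_database(
    path,
    dialect: str = "cellchat_tsv",
    complex_delimiter: str = "_",
) -> list[LRPair]:
    """Parse a ligand-receptor candidate table into :class:`LRPair` objects.

    Complex subunits are split on ``complex_delimiter``; rows identical in
    (ligand set, receptor set) are deduplicated, keeping the first.  An
    optional ``pathway`` column is carried through when present.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip().lower() for c in df.columns]
    lig_col, rec_col = _DIALECT_COLUMNS[dialect]
    for col in (lig_col, rec_col):
        if col not in df.columns:
            raise LRFormatError(f"missing required column {col!r} in {path}")
    if df.empty:
        warnings.warn(f"ligand-receptor table {path} has no rows", stacklevel=2)
        return []

    pairs: list[LRPair] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    for _, row in df.iterrows():
        lig = tuple(s for s in str(row[lig_col]).split(complex_delimiter) if s)
        rec = tuple(s for s in str(row[rec_col]).split(complex_delimiter) if s)
        if not lig or not rec:
            continue
        pathway = str(row["pathway"]) if "pathway" in df.columns else None
        pair = LRPair(
            pair_id=f"{'_'.join(lig)}::{'_'.join(rec)}",
            ligand_genes=lig,
            receptor_genes=rec,
            pathway=pathway,
        )
        if pair.key in seen:
            continue
        seen.add(pair.key)
        pairs.append(pair)
    return pairs


def collapse_complex(
    m: CountMatrix,
    genes,
    policy: str = "sum_present",
    case_insensitive: bool = False,
) -> np.ndarray | None:
    """Collapse a (possibly heteromeric) gene set to one per-spot count vector.

    Returns the element-wise sum of the member genes' columns, or ``None``
    when the set is unusable: no member present, or (``policy='strict'``) any
    member missing.
    """
    if policy not in ("sum_present", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    genes = tuple(genes)
    if case_insensitive:
        lookup = {g.upper(): g for g in m.gene_ids}
        resolved = [lookup.get(g.upper()) for g in genes]
    else:
        resolved = [g if m.has_gene(g) else None for g in genes]
    present = [g for g in resolved if g is not None]
    if not present:
        return None
    if len(present) < len(genes):
        if policy == "strict":
            return None
        logger.warning(
            "complex %s: %d of %d subunits absent; summing present subunits",
            genes, len(genes) - len(present), len(genes),
        )
    out = np.zeros(m.n_spots, dtype=np.int64)
    for g in present:
        out += m.gene_column(g)
    return out


def filter_pairs(
    m: CountMatrix,
    pairs: list[LRPair],
    min_spots: int | None = None,
    policy: str = "sum_present",
) -> list[LRPair]:
    """Keep pairs whose collapsed ligand AND receptor are each nonzero in at
    least ``min_spots`` spots (default: 10% of spots).  Pairs with an
    unusable complex are dropped."""
    if min_spots is None:
        min_spots = int(np.ceil(0.1 * m.n_spots))
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    kept = []
    for pair in pairs:
        lig = collapse_complex(m, pair.ligand_genes, policy=policy)
        rec = collapse_complex(m, pair.receptor_genes, policy=policy)
        if lig is None or rec is None:
            logger.info("pair %s unusable: complex member genes absent", pair.pair_id)
            continue
        if int((lig > 0).sum()) >= min_spots and int((rec > 0).sum()) >= min_spots:
            kept.append(pair)
    return kept
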