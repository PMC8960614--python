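"""Greedy LD clumping of instrument variants.

LD is consumed as a supplied pairwise correlation matrix (e.g. computed
from a reference panel by external tooling); variants absent from the
matrix are treated as independent.  The window is interpreted as +/-
``window_bp`` around each index variant, following the convention of
standard clumping tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .sumstats_io import SummaryStatSet

log = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Square pairwise-correlation matrix keyed by variant id."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise InputError(
                f"LD matrix shape {self.r.shape} does not match {n} variant ids"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise InputError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, id_a: str, id_b: str) -> float | None:
        """Squared correlation, or None when either variant is unknown."""
        ia = self._index.get(id_a)
        ib = self._index.get(id_b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "LDMatrix":
        """Long format: columns id_a, id_b, r; unlisted pairs are r = 0."""
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        ids = sorted(set(df["id_a"]) | set(df["id_b"]))
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        for a, b, val in df.itertuples(index=False):
            r[idx[a], idx[b]] = val
            r[idx[b], idx[a]] = val
        np.fill_diagonal(r, 1.0)
        return cls(ids, r)

    def write_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )


def greedy_clump(
    instruments: SummaryStatSet,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> SummaryStatSet:
    """Reduce instruments to quasi-independent index variants.

    Repeatedly takes the smallest-p remaining variant as an index and
    removes all same-chromosome variants within ``window_bp`` of it whose
    squared correlation with it exceeds ``r2_threshold``.  Ties on p-value
    break on (chromosome, position, variant_id) for determinism.
    Cross-chromosome pairs are always treated as independent.
    """
    df = instruments.df.sort_values(
        ["pval", "chromosome", "position", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    ids = df["variant_id"].to_numpy()
    chrom = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy()

    known = np.array([v in ld._index for v in ids])
    if not known.all():
        log.warning(
            "%s: %d instrument(s) missing from the LD matrix, treated as independent",
            instruments.trait_id, int((~known).sum()),
        )

    alive = np.ones(len(df), dtype=bool)
    keep: list[str] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(ids[i])
        if not known[i]:
            continue
        in_window = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        in_window[i] = False
        for j in np.nonzero(in_window)[0]:
            r2 = ld.r2(ids[i], ids[j])
            if r2 is not None and r2 > r2_threshold:
                alive[j] = False
    return instruments.subset(keep)


def count_rule(instruments: SummaryStatSet, min_variants: int = 10) -> bool:
    """True iff the clumped instrument has at least ``min_variants`` variants."""
    return instruments.n_variants >= min_variants
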