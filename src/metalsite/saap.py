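"""Significant amino-acid pair (SAAP) mining by hypergeometric enrichment.

A SAAP is an ordered pair of (offset, residue) assignments inside the
±w window around a candidate site, e.g. (-4C, +1P): a cysteine four
positions upstream together with a proline one position downstream of
the center.  For each pair observed anywhere in the dataset we count

* ``N`` — windows in the whole dataset,
* ``M`` — windows in the positive (binding) subset,
* ``n`` — windows containing the pair,
* ``x`` — positive windows containing the pair,

and score enrichment with the hypergeometric upper-tail probability
P(X >= x) for X ~ Hypergeom(N, M, n).  Pairs with p below a
significance level are ranked ascending by p and exported as binary
indicator features for the classifier.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import PAD, Window

PairKey = tuple[int, str, int, str]


@dataclass(frozen=True)
class SaapFeature:
    """One candidate pair with its dataset counts and p-value."""

    offset1: int
    aa1: str
    offset2: int
    aa2: str
    n: int = 0
    x: int = 0
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.offset1 >= self.offset2:
            raise ValueError("pairs are canonical: offset1 < offset2")
        if 0 in (self.offset1, self.offset2):
            raise ValueError("center offset 0 is excluded from pairs")

    @property
    def key(self) -> PairKey:
        return (self.offset1, self.aa1, self.offset2, self.aa2)

    def matches(self, window: Window) -> bool:
        """True iff the window carries both residues at the pair's offsets."""
        return (
            window.residue_at(self.offset1) == self.aa1
            and window.residue_at(self.offset2) == self.aa2
        )

    def __str__(self) -> str:
        return f"({self.offset1}{self.aa1},{self.offset2}{self.aa2})"


@dataclass
class SaapCatalog:
    """All counted pairs of a dataset, with the (N, M) window totals."""

    N: int
    M: int
    features: list[SaapFeature] = field(default_factory=list)


def window_pairs(window: Window) -> set[PairKey]:
    """The set of canonical (offset1, aa1, offset2, aa2) pairs in a window.

    The center offset 0 is excluded (it is constant within a model's
    dataset) and padding ``X`` never matches anything.
    """
    items = [
        (off, window.residue_at(off))
        for off in range(-window.w, window.w + 1)
        if off != 0 and window.residue_at(off) != PAD
    ]
    return {
        (o1, a1, o2, a2)
        for i, (o1, a1) in enumerate(items)
        for (o2, a2) in items[i + 1 :]
    }


def enumerate_pairs(windows: list[Window]) -> SaapCatalog:
    """Count every observed pair over a labeled window set.

    Counting is per-window membership (0/1), not occurrence
    multiplicity.  All windows must share the same flank width and the
    same center residue type.
    """
    if not windows:
        return SaapCatalog(N=0, M=0, features=[])
    w0, c0 = windows[0].w, windows[0].site.residue
    for win in windows:
        if win.w != w0:
            raise ValueError("windows have mixed flank widths")
        if win.site.residue != c0:
            raise ValueError(
                f"mixed center residue types ({c0} vs {win.site.residue}); "
                "mine each center type separately"
            )
    n_counts: dict[PairKey, int] = {}
    x_counts: dict[PairKey, int] = {}
    n_pos = 0
    for win in windows:
        pos = win.site.is_binding
        n_pos += pos
        for key in window_pairs(win):
            n_counts[key] = n_counts.get(key, 0) + 1
            if pos:
                x_counts[key] = x_counts.get(key, 0) + 1
    features = [
        SaapFeature(*key, n=n_counts[key], x=x_counts.get(key, 0))
        for key in sorted(n_counts)
    ]
    return SaapCatalog(N=len(windows), M=n_pos, features=features)


def _check_bounds(N: int, M: int, n: int, x: int) -> None:
    if not (0 <= M <= N and 0 <= x <= n <= N and x <= M and n - x <= N - M):
        raise ValueError(
            f"invalid hypergeometric parameters N={N}, M={M}, n={n}, x={x}"
        )


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_pmf(N: int, M: int, n: int, x: int) -> float:
    """P(X = x) for X ~ Hypergeom(N, M, n): C(M,x) C(N-M,n-x) / C(N,n).

    Computed in log-space for stability at large counts.
    """
    _check_bounds(N, M, n, x)
    return math.exp(_log_comb(M, x) + _log_comb(N - M, n - x) - _log_comb(N, n))


def saap_pvalue(N: int, M: int, n: int, x: int, mode: str = "tail") -> float:
    """Enrichment p-value of a pair observed in x of n windows.

    ``mode="tail"`` (default): the upper-tail sum P(X >= x), the
    probability of enrichment at least as extreme under random draws.
    ``mode="point"``: the point-mass P(X = x) alone.
    """
    _check_bounds(N, M, n, x)
    if mode == "point":
        return hypergeom_pmf(N, M, n, x)
    if mode != "tail":
        raise ValueError(f"unknown p-value mode {mode!r}")
    logs = [
        _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
        for i in range(x, min(n, M) + 1)
    ]
    if not logs:
        return 0.0  # unreachable under the bound checks
    m = max(logs)
    total = math.exp(m) * math.fsum(math.exp(v - m) for v in logs)
    return min(total, 1.0)


def compute_pvalues(catalog: SaapCatalog, mode: str = "tail") -> SaapCatalog:
    """Return a copy of the catalog with p-values filled in."""
    feats = [
        replace(f, p_value=saap_pvalue(catalog.N, catalog.M, f.n, f.x, mode))
        for f in catalog.features
    ]
    return SaapCatalog(N=catalog.N, M=catalog.M, features=feats)


def rank_saaps(catalog: SaapCatalog, alpha: float = 0.05) -> SaapCatalog:
    """Keep pairs with p < alpha, ascending by p.

    Ties are broken by (offset1, aa1, offset2, aa2) lexicographic order,
    so the ranking is total and stable across runs.
    """
    if any(f.p_value is None for f in catalog.features):
        raise ValueError("compute_pvalues before ranking")
    kept = [f for f in catalog.features if f.p_value < alpha]
    kept.sort(key=lambda f: (f.p_value, f.key))
    return SaapCatalog(N=catalog.N, M=catalog.M, features=kept)


def mine_saaps(
    windows: list[Window], alpha: float = 0.05, mode: str = "tail"
) -> SaapCatalog:
    """Convenience: enumerate, score and rank in one call."""
    return rank_saaps(compute_pvalues(enumerate_pairs(windows), mode), alpha)


def encode_saap_indicators(
    window: Window, features: list[SaapFeature]
) -> np.ndarray:
    """Binary vector: element k is 1 iff the window contains feature k's pair."""
    present = window_pairs(window)
    return np.array(
        [1.0 if f.key in present else 0.0 for f in features]
    )


def indicator_matrix(
    windows: list[Window], features: list[SaapFeature]
) -> np.ndarray:
    """Stack of indicator vectors, one row per window."""
    if not features:
        return np.zeros((len(windows), 0))
    return np.asarray([encode_saap_indicators(w, features) for w in windows])


CATALOG_COLUMNS = ("offset1", "aa1", "offset2", "aa2", "n", "x", "p_value")


def write_catalog(catalog: SaapCatalog, path: str | Path) -> None:
    """Export a catalog as headered TSV (p-values in scientific notation)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("#N", catalog.N, "M", catalog.M))
        writer.writerow(CATALOG_COLUMNS)
        for f in catalog.features:
            p = "" if f.p_value is None else format(f.p_value, ".6e")
            writer.writerow((f.offset1, f.aa1, f.offset2, f.aa2, f.n, f.x, p))


def read_catalog(path: str | Path) -> SaapCatalog:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        head = next(reader)
        if len(head) != 4 or head[0] != "#N":
            raise ValueError(f"{path}: not a SAAP catalog (missing #N header)")
        N, M = int(head[1]), int(head[3])
        cols = tuple(next(reader))
        if cols != CATALOG_COLUMNS:
            raise ValueError(f"{path}: unexpected columns {cols}")
        feats = []
        for row in reader:
            if not row:
                continue
            feats.append(
                SaapFeature(
                    offset1=int(row[0]),
                    aa1=row[1],
                    offset2=int(row[2]),
                    aa2=row[3],
                    n=int(row[4]),
                    x=int(row[5]),
                    p_value=float(row[6]) if row[6] else None,
                )
            )
    return SaapCatalog(N=N, M=M, features=feats)
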