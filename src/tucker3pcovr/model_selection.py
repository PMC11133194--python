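"""Rank-grid enumeration and CHULL model selection.

The Tucker3 complexity (R1, R2, R3) is chosen by fitting all valid rank
triples up to a maximum, plotting loss against total number of components
c = R1 + R2 + R3, retaining the lower-left convex hull of that scatter, and
selecting the hull model with the largest st-ratio

    st_i = [(f_{i-1} - f_i) / (c_i - c_{i-1})] / [(f_i - f_{i+1}) / (c_{i+1} - c_i)]

i.e. the point where the fit-per-component payoff drops most sharply.  Hull
endpoints have no st-ratio and are never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CoupledDataset, Ranks, Tucker3PCovRFit
from .estimation import FitConfig, fit

__all__ = ["ChullEntry", "ChullResult", "enumerate_ranks", "chull_select", "select_ranks"]


@dataclass(frozen=True)
class ChullEntry:
    """One candidate model: its ranks (a :class:`Ranks` or any integer
    triple — abstract scans need no Tucker validity) and its loss."""

    ranks: object
    loss: float

    @property
    def key(self) -> tuple[int, int, int]:
        if isinstance(self.ranks, Ranks):
            return self.ranks.astuple()
        return tuple(int(v) for v in self.ranks)

    @property
    def complexity(self) -> int:
        return sum(self.key)


@dataclass
class ChullResult:
    """Outcome of a CHULL scan over candidate complexities."""

    entries: list[ChullEntry]
    on_hull: np.ndarray  # bool per entry
    st: dict[int, float]  # complexity -> st-ratio (hull-interior points only)
    selected: object
    warning: str | None = None

    def as_table(self):
        """The scan as a pandas DataFrame (ranks, complexity, loss, on_hull, st)."""
        import pandas as pd

        rows = []
        for e, h in zip(self.entries, self.on_hull):
            rows.append(
                {
                    "R1": e.key[0],
                    "R2": e.key[1],
                    "R3": e.key[2],
                    "complexity": e.complexity,
                    "loss": e.loss,
                    "on_hull": bool(h),
                    "st": self.st.get(e.complexity, np.nan) if h else np.nan,
                    "selected": e.ranks == self.selected,
                }
            )
        return pd.DataFrame(rows)


def enumerate_ranks(
    dims: tuple[int, int, int, int], max_ranks: tuple[int, int, int]
) -> list[Ranks]:
    """All valid Tucker3 complexities between (1,1,1) and ``max_ranks``.

    ``dims`` is (I, J, K, L).  A triple is valid when each rank is at most
    the product of the other two and fits within the data dimensions.
    """
    I, J, K, L = dims
    m1 = min(max_ranks[0], I, L + J * K)
    m2 = min(max_ranks[1], J)
    m3 = min(max_ranks[2], K)
    out = []
    for r1 in range(1, m1 + 1):
        for r2 in range(1, m2 + 1):
            for r3 in range(1, m3 + 1):
                if r1 <= r2 * r3 and r2 <= r1 * r3 and r3 <= r1 * r2:
                    out.append(Ranks(r1, r2, r3))
    return out


def _per_complexity_minimum(entries: list[ChullEntry]) -> list[ChullEntry]:
    """Best (lowest-loss) model per complexity; fit ties broken
    lexicographically on (R1, R2, R3)."""
    best: dict[int, ChullEntry] = {}
    for e in sorted(entries, key=lambda e: (e.complexity, e.loss, e.key)):
        best.setdefault(e.complexity, e)
    return [best[c] for c in sorted(best)]


def _lower_left_hull(points: list[ChullEntry]) -> list[ChullEntry]:
    """Lower-left convex hull of (complexity, loss) points, complexities
    already unique and sorted.  Keeps only points with strictly decreasing
    loss, then prunes points above a chord (monotone-chain lower hull)."""
    mono: list[ChullEntry] = []
    for p in points:
        if not mono or p.loss < mono[-1].loss:
            mono.append(p)
    hull: list[ChullEntry] = []
    for p in mono:
        while len(hull) >= 2:
            (c1, f1), (c2, f2) = (hull[-2].complexity, hull[-2].loss), (
                hull[-1].complexity,
                hull[-1].loss,
            )
            # pop the middle point only when strictly above the chord
            # (within rounding), so collinear scans keep their interior
            # points (each with st = 1)
            lhs = (f2 - f1) * (p.complexity - c1)
            rhs = (p.loss - f1) * (c2 - c1)
            eps = 1e-12 * max(1.0, abs(f1), abs(f2), abs(p.loss)) * (
                p.complexity - c1
            )
            if lhs > rhs + eps:
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def chull_select(entries: list[ChullEntry]) -> ChullResult:
    """Run the CHULL procedure on (ranks, loss) candidates.

    Hull-interior points get an st-ratio; the largest st wins, with ties
    broken toward lower complexity.  If fewer than three hull points exist,
    the lowest-loss model is returned with a warning.
    """
    if not entries:
        raise ValueError("no candidate models")
    reduced = _per_complexity_minimum(entries)
    hull = _lower_left_hull(reduced)
    hull_keys = {e.key for e in hull}
    on_hull = np.array([e.key in hull_keys for e in entries])

    st: dict[int, float] = {}
    warning = None
    if len(hull) < 3:
        warning = (
            "fewer than 3 convex-hull points: st-ratios are undefined; "
            "selecting the lowest-loss model"
        )
        selected = min(entries, key=lambda e: (e.loss, e.complexity, e.key)).ranks
        return ChullResult(entries, on_hull, st, selected, warning)

    for i in range(1, len(hull) - 1):
        prev_, cur, nxt = hull[i - 1], hull[i], hull[i + 1]
        num = (prev_.loss - cur.loss) / (cur.complexity - prev_.complexity)
        den = (cur.loss - nxt.loss) / (nxt.complexity - cur.complexity)
        st[cur.complexity] = num / den if den > 0 else np.inf
    # ties (within rounding) go to the lower complexity
    top = max(st.values())
    tie_band = 1e-9 * max(1.0, abs(top))
    best_c = min(c for c in st if st[c] >= top - tie_band)
    selected = next(e.ranks for e in hull if e.complexity == best_c)
    return ChullResult(entries, on_hull, st, selected, warning)


def select_ranks(
    dataset: CoupledDataset,
    alpha: float,
    max_ranks: tuple[int, int, int] = (4, 4, 4),
    config: FitConfig | None = None,
    **config_kwargs,
) -> tuple[ChullResult, dict[tuple[int, int, int], Tucker3PCovRFit]]:
    """Fit every valid complexity up to ``max_ranks`` and run CHULL.

    Returns the selection result and the per-complexity fitted models.
    Extra keyword arguments are forwarded to :class:`FitConfig`.
    """
    grid = enumerate_ranks(dataset.shape, max_ranks)
    fits: dict[tuple[int, int, int], Tucker3PCovRFit] = {}
    entries = []
    for ranks in grid:
        if config is None:
            cfg = FitConfig(alpha=alpha, ranks=ranks, **config_kwargs)
        else:
            cfg = replace(config, alpha=alpha, ranks=ranks)
        f = fit(dataset, cfg)
        fits[ranks.astuple()] = f
        entries.append(ChullEntry(ranks=ranks, loss=f.loss))
    return chull_select(entries), fits
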