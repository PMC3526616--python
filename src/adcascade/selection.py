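"""Student t-tests on embedding components and CSF markers; feature selection.

Shape features entering the classifiers are only the embedding components
with a significant two-group difference under a pooled-variance Student
t-test (alpha = 0.05, two-tailed, no multiple-testing correction by
default — per-component reporting; an optional Benjamini-Hochberg switch
is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError
from .embedding import ShapeEmbedding

#: composite group used in contrasts: "MCI" pools stable and converting MCI
GROUP_ALIASES = {"MCI": ("MCI_s", "MCI_c")}


def group_mask(labels, group: str) -> np.ndarray:
    """Boolean mask for a (possibly composite) diagnostic group."""
    labels = np.asarray(labels)
    members = GROUP_ALIASES.get(group, (group,))
    return np.isin(labels, members)


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student t (df = nx + ny - 2), two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateStatisticError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


@dataclass
class SelectionResult:
    """Per-feature t statistics and the indices selected at level alpha.

    ``selected`` uses 1-based component numbering, matching the way shape
    components are conventionally reported (component 1 = leading).
    """

    contrast: tuple
    t: np.ndarray
    p: np.ndarray
    selected: list
    alpha: float

    def __post_init__(self) -> None:
        assert all(1 <= i <= len(self.p) for i in self.selected)


def select_components(
    E: ShapeEmbedding,
    labels,
    contrast: tuple,
    alpha: float = 0.05,
    fdr: bool = False,
) -> SelectionResult:
    """Test every component between the two contrast groups; keep p < alpha.

    With ``fdr=True`` the per-component p-values are Benjamini-Hochberg
    adjusted before thresholding.
    """
    labels = np.asarray(labels)
    ga, gb = contrast
    mask_a, mask_b = group_mask(labels, ga), group_mask(labels, gb)
    if not mask_a.any():
        raise ValueError(f"group {ga!r} absent from labels")
    if not mask_b.any():
        raise ValueError(f"group {gb!r} absent from labels")
    ts, ps = [], []
    for c in range(E.n_components):
        col = E.coordinates[:, c]
        t, p = two_sample_t(col[mask_a], col[mask_b])
        ts.append(t)
        ps.append(p)
    ps_arr = np.array(ps)
    crit = _bh_adjust(ps_arr) if fdr else ps_arr
    selected = [i + 1 for i in range(len(ps)) if crit[i] < alpha]
    return SelectionResult(tuple(contrast), np.array(ts), ps_arr, selected, alpha)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
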