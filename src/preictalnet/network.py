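"""Graph-theoretic characterization of interrelation matrices.

Node strength is the mean absolute matrix element connecting one channel
with all others.  Degree assortativity is the Pearson correlation of
endpoint degrees over the (binarized) edge list: negative for star-like
networks, positive for uniformly integrated ones, undefined when all
endpoint degrees coincide.  Core nodes are identified from the largest
adjacent gap in the sorted node strengths, on a linear and a logarithmic
scale, accepted only when prominent against the typical gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interrelation import InterrelationMatrix

__all__ = [
    "NetworkMetrics",
    "node_strength",
    "degree_assortativity",
    "core_nodes",
    "normalized_share",
    "format_percent",
    "matrix_metrics",
]


@dataclass
class NetworkMetrics:
    """Per-matrix summary: node strengths, assortativity and core split."""

    node_strength: np.ndarray
    assortativity: float  # NaN when undefined (zero degree variance)
    core_set: frozenset
    kind: str
    no_core: bool = False
    channel_labels: list | None = None
    gap_diagnostics: dict = field(default_factory=dict)

    @property
    def assortativity_defined(self) -> bool:
        return np.isfinite(self.assortativity)


def _values(M) -> np.ndarray:
    return M.values if isinstance(M, InterrelationMatrix) else np.asarray(M, float)


def node_strength(M) -> np.ndarray:
    """NS_i = mean over j != i of |M_ij|."""
    v = np.abs(_values(M))
    n = v.shape[0]
    if n < 2:
        raise ValueError("node strength requires >= 2 channels")
    off = v.sum(axis=1) - np.diag(v)
    return off / (n - 1)


def degree_assortativity(M, weighted: bool = False) -> float:
    """Pearson correlation of endpoint degrees over the directed edge list.

    Edges are the nonzero off-diagonal entries of the (surrogate-corrected)
    matrix; each undirected edge contributes both orientations.  With
    ``weighted=True`` degrees are weighted by |M_ij| instead of binarized.
    Returns NaN when either endpoint degree sequence has zero variance
    (e.g. a cycle, where all degrees are equal).
    """
    v = np.abs(_values(M)).copy()
    np.fill_diagonal(v, 0.0)
    adj = v if weighted else (v > 0).astype(float)
    deg = adj.sum(axis=1)
    ii, jj = np.nonzero(v)
    if ii.size == 0:
        raise ValueError("assortativity undefined for an edgeless matrix")
    x, y = deg[ii], deg[jj]  # includes both orientations of every edge
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def core_nodes(
    ns: np.ndarray, prominence: float = 2.0
) -> tuple[frozenset, dict]:
    """Split channels into core and periphery at the largest strength gap.

    Channels are sorted by node strength (descending); adjacent gaps are
    computed on the linear scale and, for strictly positive values, on the
    logarithmic scale (zeros always fall to the periphery).  On each scale
    the candidate split is the largest gap; a scale is accepted when its
    largest gap exceeds ``prominence`` times that scale's median gap.  If
    both scales qualify, the one with the larger gap-to-median ratio wins.
    If neither is prominent the core set is empty and ``no_core`` is set —
    the situation of near-uniform strengths, where no core-periphery
    structure exists.

    Returns ``(core_indices, diagnostics)``.
    """
    ns = np.asarray(ns, float)
    if ns.size < 3:
        raise ValueError("core detection requires >= 3 channels")
    if np.any(ns < 0):
        raise ValueError("node strengths must be nonnegative")
    order = np.argsort(-ns, kind="stable")
    sorted_ns = ns[order]

    candidates = {}  # scale -> (ratio, split_position)
    lin_gaps = sorted_ns[:-1] - sorted_ns[1:]
    candidates["linear"] = _gap_candidate(lin_gaps, prominence)

    pos = sorted_ns[sorted_ns > 0]
    log_gaps = np.diff(-np.log(pos)) if pos.size >= 2 else np.array([])
    candidates["log"] = _gap_candidate(log_gaps, prominence)

    diagnostics = {
        "sorted_ns": sorted_ns,
        "order": order,
        "linear_gaps": lin_gaps,
        "log_gaps": log_gaps,
        "candidates": candidates,
    }
    accepted = {k: v for k, v in candidates.items() if v is not None}
    if not accepted:
        diagnostics["accepted_scale"] = None
        return frozenset(), diagnostics
    scale = max(accepted, key=lambda k: accepted[k][0])
    split = accepted[scale][1]
    diagnostics["accepted_scale"] = scale
    diagnostics["split_position"] = split
    return frozenset(int(i) for i in order[: split + 1]), diagnostics


def _gap_candidate(gaps: np.ndarray, prominence: float):
    if gaps.size == 0:
        return None
    k = int(np.argmax(gaps))
    largest = gaps[k]
    med = float(np.median(gaps))
    if largest <= 0 or largest <= prominence * med:
        return None
    ratio = largest / med if med > 0 else np.inf
    return (ratio, k)


def normalized_share(ns: np.ndarray, subset) -> float:
    """Overrepresentation factor of a channel subset's node strength.

    (subset share of total NS) / (subset share of channels); 1 under a
    uniform distribution of interrelation strength, > 1 when the subset is
    overrepresented.
    """
    ns = np.asarray(ns, float)
    idx = np.asarray(sorted(subset), int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    total = ns.sum()
    if total <= 0:
        raise ValueError("total node strength is zero")
    observed = ns[idx].sum() / total
    expected = idx.size / ns.size
    return float(observed / expected)


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage, rounding half away from zero."""
    scaled = fraction * 100.0 * 10**decimals
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return f"{rounded / 10**decimals:.{decimals}f}"


def matrix_metrics(M: InterrelationMatrix, prominence: float = 2.0) -> NetworkMetrics:
    """Bundle node strength, assortativity and core detection for one matrix."""
    ns = node_strength(M)
    try:
        r = degree_assortativity(M)
    except ValueError:
        r = float("nan")
    core, diag = core_nodes(ns, prominence=prominence)
    return NetworkMetrics(
        node_strength=ns,
        assortativity=r,
        core_set=core,
        kind=M.kind,
        no_core=(len(core) == 0),
        channel_labels=M.channel_labels,
        gap_diagnostics=diag,
    )
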