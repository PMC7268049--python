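"""Cross-epoch reproducibility of interrelation patterns.

Epoch-averaged matrices are first *laterality matched*: channels of the
standardized bilateral implantation (Am/Hi electrodes, up to 8 contacts) are
rearranged into one fixed order — amygdala then hippocampus of the focal
hemisphere, then the same for the nonfocal hemisphere — so that matrices
from different epochs and patients are element-wise comparable.  Missing
contacts are padded with masked (NaN) entries and excluded pairwise.

An uncentered PCA across epochs of the vectorized upper triangles then
quantifies how reproducible the patterns are: the explained variance of the
dominant component, its *collectivity* (|sum of epoch scores| / sum of
|epoch scores|, 1 when every epoch contributes with the same sign) and its
*symmetry* (Pearson correlation between the component pattern and its
hemisphere-swapped counterpart).  Similarity of two individual matrices is
tested with a one-sided Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .interrelation import InterrelationMatrix
from .io import parse_channel_label

__all__ = [
    "PCAResult",
    "laterality_match",
    "pca_components",
    "mantel_test",
]

ELECTRODE_ORDER = ("Am", "Hi")


@dataclass
class PCAResult:
    """Cross-epoch PCA of laterality-matched interrelation matrices."""

    patterns: np.ndarray  # components x channels x channels, NaN at masked slots
    explained_variance: np.ndarray  # fractions, summing to 1 over all components
    collectivity: np.ndarray  # per reported component, in [0, 1]
    symmetry: np.ndarray  # per reported component, in [-1, 1]
    scores: np.ndarray  # epochs x components
    slot_labels: list


def canonical_slots(n_contacts: int = 8) -> list[str]:
    """Fixed slot order: Am-focal, Hi-focal, Am-nonfocal, Hi-nonfocal."""
    return [
        f"{el}-{side}{c:02d}"
        for side in ("focal", "nonfocal")
        for el in ELECTRODE_ORDER
        for c in range(1, n_contacts + 1)
    ]


def laterality_match(
    M: InterrelationMatrix, metadata, n_contacts: int = 8
) -> tuple[np.ndarray, list[str]]:
    """Reorder a matrix into the canonical focal-first slot layout.

    ``metadata`` supplies per-channel ``label`` and ``focal`` columns in the
    matrix's channel order.  Slots without a recorded contact are NaN.
    Returns ``(matrix, slot_labels)`` with shape (4*n_contacts, 4*n_contacts).
    """
    labels = list(metadata["label"])
    focal = np.asarray(metadata["focal"], bool)
    if M.values.shape[0] != len(labels):
        raise ValueError("metadata does not match matrix dimension")
    slots = canonical_slots(n_contacts)
    slot_index = {s: k for k, s in enumerate(slots)}
    positions = np.full(len(labels), -1, dtype=int)
    for i, lab in enumerate(labels):
        electrode, _side, contact = parse_channel_label(lab)
        if electrode not in ELECTRODE_ORDER:
            raise ValueError(f"channel {lab!r} not mappable to the Am/Hi scheme")
        if not 1 <= contact <= n_contacts:
            raise ValueError(f"channel {lab!r} has contact outside 1..{n_contacts}")
        key = f"{electrode}-{'focal' if focal[i] else 'nonfocal'}{contact:02d}"
        positions[i] = slot_index[key]
    if len(set(positions)) != len(labels):
        raise ValueError("two channels map to the same canonical slot")

    out = np.full((len(slots), len(slots)), np.nan)
    out[np.ix_(positions, positions)] = M.values
    np.fill_diagonal(out, 0.0)
    return out, slots


def _hemisphere_swap_permutation(n_slots: int) -> np.ndarray:
    half = n_slots // 2
    return np.concatenate([np.arange(half, n_slots), np.arange(half)])


def pca_components(matrices, n_report: int = 3) -> PCAResult:
    """Uncentered PCA of the vectorized upper triangles across epochs.

    Only matrix elements observed in every epoch enter the decomposition.
    No mean pattern is subtracted, so the dominant component represents the
    common pattern and collectivity measures how constructively the epochs
    combine into it.
    """
    stack = np.stack([np.asarray(m, float) for m in matrices])
    if stack.shape[0] < 2:
        raise ValueError("PCA requires >= 2 epochs")
    n_slots = stack.shape[1]
    iu, ju = np.triu_indices(n_slots, k=1)
    vecs = stack[:, iu, ju]  # epochs x pairs
    valid = np.all(np.isfinite(vecs), axis=0)
    if not valid.any():
        raise ValueError("no matrix element observed in every epoch")
    X = vecs[:, valid]
    if not np.any(X != 0):
        raise ValueError("all matrices are zero; PCA undefined")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # orient each component so the epochs' net contribution is positive
    flip = np.where(np.sum(U * s, axis=0) < 0, -1.0, 1.0)
    U, Vt = U * flip, Vt * flip[:, None]

    explained = s**2 / np.sum(s**2)
    scores = U * s  # epochs x components
    n_report = min(n_report, s.size)

    swap = _hemisphere_swap_permutation(n_slots)
    patterns = np.full((n_report, n_slots, n_slots), np.nan)
    collectivity = np.empty(n_report)
    symmetry = np.empty(n_report)
    for k in range(n_report):
        pat = np.full((n_slots, n_slots), np.nan)
        row = np.full(iu.size, np.nan)
        row[valid] = Vt[k]
        pat[iu, ju] = row
        pat[ju, iu] = row
        np.fill_diagonal(pat, 0.0)
        patterns[k] = pat
        denom = np.sum(np.abs(scores[:, k]))
        collectivity[k] = np.abs(np.sum(scores[:, k])) / denom if denom > 0 else 0.0
        swapped = pat[np.ix_(swap, swap)]
        both = np.isfinite(pat) & np.isfinite(swapped)
        np.fill_diagonal(both, False)
        a, b = pat[both], swapped[both]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            symmetry[k] = 0.0
        else:
            symmetry[k] = float(np.corrcoef(a, b)[0, 1])

    return PCAResult(
        patterns=patterns,
        explained_variance=explained,
        collectivity=collectivity,
        symmetry=symmetry,
        scores=scores[:, :n_report],
        slot_labels=canonical_slots(n_slots // 4),
    )


def mantel_test(
    A, B, n_perm: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """One-sided Mantel permutation test for positive matrix association.

    r is the Pearson correlation of the upper-triangle off-diagonal elements
    (pairwise-complete over masked entries).  The null is generated by
    jointly permuting rows and columns of B with random node permutations;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    A = np.asarray(A.values if isinstance(A, InterrelationMatrix) else A, float)
    B = np.asarray(B.values if isinstance(B, InterrelationMatrix) else B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must share one square shape")
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)

    def corr(bmat):
        a, b = A[iu, ju], bmat[iu, ju]
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 3 or a.std() == 0 or b.std() == 0:
            raise ValueError("zero-variance off-diagonals; Mantel r undefined")
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += corr(B[np.ix_(perm, perm)]) >= r_obs
    return r_obs, (1 + count) / (1 + n_perm)
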