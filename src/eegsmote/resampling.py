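"""Minority oversampling for imbalanced seizure/nonseizure data.

Five resamplers share one exact k-nearest-neighbour backend:

``ros``
    Random oversampling: duplicate minority rows with replacement.
``smote``
    Classic SMOTE: interpolate between a minority row and one of its
    minority-class nearest neighbours.
``blsmote``
    Borderline-SMOTE-1: restrict SMOTE parents to "danger" minority rows,
    those with at least half (but not all) majority-class neighbours.
``svmsmote``
    Parents are minority-class support vectors of a soft-margin linear SVM.
``bnnsmote``
    Boundary-nearest-neighbour SMOTE: (1) drop noise minority rows (all-
    majority neighbourhoods), (2) find majority rows sitting on the class
    boundary, (3) take the minority rows adjacent to those boundary
    majority rows as the hard-to-learn parent set, (4) interpolate each
    parent toward a randomly chosen clean minority row.

All resamplers are deterministic given (data, config): randomness comes
from a single ``numpy`` generator seeded from ``ResampleConfig.seed`` and
consumed in the documented order (parent, partner, delta) per synthetic
row.  Majority rows always pass through unmodified and in order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import LabeledDataset, SyntheticProvenance

__all__ = [
    "NeighborTable", "ResampleConfig", "ResampleResult", "ResamplerError",
    "compute_neighbors", "filter_noise", "boundary_majority",
    "danger_minority", "synthesize_samples",
    "bnnsmote", "ros", "smote", "blsmote", "svmsmote",
    "RESAMPLERS", "resample",
]


class ResamplerError(RuntimeError):
    """Raised when a resampler cannot satisfy its contract."""


# ---------------------------------------------------------------------------
# shared kNN machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborTable:
    """Exact k nearest neighbours per query row.

    ``indices[i]`` are reference-row indices sorted by ascending distance
    to query row ``i``; ties broken by lower reference index.  A query row
    known to coincide with a reference row never lists itself.
    """

    indices: np.ndarray   # (n_query, k) int
    distances: np.ndarray  # (n_query, k) float, sorted ascending per row


def compute_neighbors(X_ref: np.ndarray, X_query: np.ndarray, k: int,
                      metric: str = "euclidean",
                      self_indices: np.ndarray | None = None,
                      ) -> NeighborTable:
    """Exact brute-force k nearest neighbours.

    Parameters
    ----------
    X_ref, X_query : arrays of shape (n_ref, d) and (n_query, d)
    k : number of neighbours; must be < n_ref (minus one per excluded self)
    metric : any metric name :func:`scipy.spatial.distance.cdist` accepts
    self_indices : optional array mapping each query row to the reference
        row it *is*, which is then excluded from its own neighbour list.
        When ``X_query is X_ref`` this defaults to ``arange(n_ref)``.

    Ties in distance are broken by the lower reference index (stable sort).
    """
    X_ref = np.asarray(X_ref, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    n_ref = X_ref.shape[0]
    if self_indices is None and X_query is X_ref:
        self_indices = np.arange(n_ref)
    n_excluded = 1 if self_indices is not None else 0
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_ref - n_excluded:
        raise ValueError(
            f"k={k} exceeds the {n_ref - n_excluded} available reference points")

    D = cdist(X_query, X_ref, metric=metric)
    if self_indices is not None:
        D[np.arange(len(X_query)), np.asarray(self_indices, int)] = np.inf
    # stable argsort on distances => equal distances keep ascending ref index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(D, order, axis=1)
    return NeighborTable(indices=order, distances=dists)


# ---------------------------------------------------------------------------
# configuration / result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResampleConfig:
    """Knobs shared by all resamplers.

    k_noise, k_boundary, k_danger : neighbourhood sizes for the noise
        test, the boundary-majority test and danger-set membership /
        SMOTE partner choice.  The SMOTE-family convention of 5 is the
        default for all three.
    target_ratio : desired minority/majority count ratio after
        resampling, in (0, 1]; 1.0 means fully balanced.
    metric : distance metric name (Euclidean on raw features by default;
        feature scaling is the caller's responsibility).
    seed : seeds the single generator all random draws come from.
    keep_noise : if True, BNNSMOTE retains noise-flagged minority rows in
        the output (they are still never synthesis parents).
    partner_mode : BNNSMOTE partner choice — "uniform" over all clean
        minority rows (default) or "knn" restricted to the parent's
        k_danger clean-minority neighbours.
    """

    k_noise: int = 5
    k_boundary: int = 5
    k_danger: int = 5
    target_ratio: float = 1.0
    metric: str = "euclidean"
    seed: int = 0
    keep_noise: bool = False
    partner_mode: str = "uniform"

    def __post_init__(self) -> None:
        for name in ("k_noise", "k_boundary", "k_danger"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must be in (0, 1]")
        if self.partner_mode not in ("uniform", "knn"):
            raise ValueError("partner_mode must be 'uniform' or 'knn'")


@dataclass
class ResampleResult:
    """Output of any resampler.

    ``dataset`` holds the resampled data: all original rows that were kept
    (majority rows unmodified, in original order, interleaved exactly as
    in the input) followed by ``n_synth`` synthetic minority rows.
    ``provenance[i]`` documents synthetic row i; its indices refer to rows
    of the *input* dataset.  ``kept_indices`` maps every non-synthetic
    output row back to its input row.
    """

    dataset: LabeledDataset
    n_synth: int
    noise_indices: np.ndarray
    danger_indices: np.ndarray
    provenance: list[SyntheticProvenance]
    kept_indices: np.ndarray

    @property
    def synthetic_rows(self) -> np.ndarray:
        if self.n_synth == 0:
            return self.dataset.X[:0]
        return self.dataset.X[-self.n_synth:]


# ---------------------------------------------------------------------------
# BNNSMOTE building blocks
# ---------------------------------------------------------------------------

def _check_two_classes(data: LabeledDataset) -> None:
    if len(data.minority_indices) == 0:
        raise ResamplerError("no minority (seizure) samples present")
    if len(data.majority_indices) == 0:
        raise ResamplerError("no majority (nonseizure) samples present")


def filter_noise(data: LabeledDataset, k_noise: int = 5,
                 metric: str = "euclidean",
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split minority rows into clean and noise.

    A minority row is noise iff *all* of its ``k_noise`` nearest
    neighbours in the full dataset (self excluded) are majority class —
    it sits isolated inside the majority region and would only smear the
    class boundary if used for synthesis.

    Returns ``(clean_minority, noise)`` index arrays; their union is the
    set of all minority indices and they are disjoint.
    """
    _check_two_classes(data)
    mino = data.minority_indices
    nt = compute_neighbors(data.X, data.X[mino], k_noise, metric=metric,
                           self_indices=mino)
    neigh_labels = data.y[nt.indices]          # (n_minority, k)
    is_noise = (neigh_labels == 0).all(axis=1)
    return mino[~is_noise], mino[is_noise]


def boundary_majority(data: LabeledDataset, clean_minority: np.ndarray,
                      k_boundary: int = 5, metric: str = "euclidean",
                      noise: np.ndarray | None = None) -> np.ndarray:
    """Majority rows on the class boundary.

    A majority row qualifies iff its ``k_boundary`` nearest neighbours —
    computed within the dataset with noise-flagged minority rows removed —
    contain at least one clean minority row.  May be empty.
    """
    clean_minority = np.asarray(clean_minority, int)
    if len(clean_minority) == 0:
        raise ResamplerError("clean_minority must be nonempty")
    maj = data.majority_indices
    noise = np.asarray(noise, int) if noise is not None else np.empty(0, int)
    # reference set: everything except noise minority rows
    ref_rows = np.setdiff1d(np.arange(data.n_samples), noise)
    pos_in_ref = {int(r): i for i, r in enumerate(ref_rows)}
    k = min(k_boundary, len(ref_rows) - 1)
    nt = compute_neighbors(data.X[ref_rows], data.X[maj], k, metric=metric,
                           self_indices=np.array([pos_in_ref[int(m)] for m in maj]))
    neigh_rows = ref_rows[nt.indices]
    clean_set = np.zeros(data.n_samples, bool)
    clean_set[clean_minority] = True
    has_clean = clean_set[neigh_rows].any(axis=1)
    return maj[has_clean]


def danger_minority(data: LabeledDataset, clean_minority: np.ndarray,
                    boundary_maj: np.ndarray, k_danger: int = 5,
                    metric: str = "euclidean",
                    noise: np.ndarray | None = None) -> np.ndarray:
    """The hard-to-learn minority set: clean minority rows adjacent to the
    boundary majority rows.

    A clean minority row is in danger iff it appears among the
    ``k_danger`` nearest neighbours of at least one boundary-majority row
    (union over boundary rows; neighbours computed with noise rows
    excluded).  If ``boundary_maj`` is empty, falls back to the
    borderline rule: clean minority rows with between k_danger/2 and
    k_danger - 1 majority-class neighbours.
    """
    clean_minority = np.asarray(clean_minority, int)
    if len(clean_minority) == 0:
        raise ResamplerError("clean_minority must be nonempty")
    boundary_maj = np.asarray(boundary_maj, int)
    if len(boundary_maj) == 0:
        # fallback: Borderline-SMOTE danger rule on the clean minority
        return _borderline_danger(data, clean_minority, k_danger, metric)
    noise = np.asarray(noise, int) if noise is not None else np.empty(0, int)
    ref_rows = np.setdiff1d(np.arange(data.n_samples), noise)
    pos_in_ref = {int(r): i for i, r in enumerate(ref_rows)}
    k = min(k_danger, len(ref_rows) - 1)
    nt = compute_neighbors(data.X[ref_rows], data.X[boundary_maj], k,
                           metric=metric,
                           self_indices=np.array([pos_in_ref[int(m)]
                                                  for m in boundary_maj]))
    neigh_rows = np.unique(ref_rows[nt.indices])
    return np.intersect1d(neigh_rows, clean_minority)


def _borderline_danger(data: LabeledDataset, minority: np.ndarray,
                       k: int, metric: str) -> np.ndarray:
    """Borderline-SMOTE-1 DANGER rule: k/2 <= m' < k majority neighbours."""
    minority = np.asarray(minority, int)
    k = min(k, data.n_samples - 1)
    nt = compute_neighbors(data.X, data.X[minority], k, metric=metric,
                           self_indices=minority)
    m_prime = (data.y[nt.indices] == 0).sum(axis=1)
    in_danger = (m_prime >= k / 2) & (m_prime < k)
    return minority[in_danger]


def synthesize_samples(data: LabeledDataset, danger: np.ndarray,
                       clean_minority: np.ndarray, n_new: int,
                       rng: np.random.Generator,
                       partner_mode: str = "uniform",
                       k_partner: int = 5, metric: str = "euclidean",
                       ) -> tuple[np.ndarray, list[SyntheticProvenance]]:
    """Interpolate ``n_new`` synthetic minority rows.

    Each row is ``x_p + delta * (x_q - x_p)`` with parent p uniform over
    ``danger`` (or over ``clean_minority`` if danger is empty), partner q
    uniform over ``clean_minority \\ {p}`` (or over p's k nearest clean
    minority neighbours when ``partner_mode='knn'``) and
    delta ~ Uniform(0, 1).  The rng is consumed in the order
    (parent, partner, delta) per row, so runs are replayable.
    """
    danger = np.asarray(danger, int)
    clean_minority = np.asarray(clean_minority, int)
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if len(clean_minority) < 2:
        raise ResamplerError(
            "synthesis needs at least two clean minority samples")
    parents_pool = danger if len(danger) else clean_minority
    if len(danger) == 0:
        warnings.warn("danger set empty; falling back to all clean minority "
                      "rows as synthesis parents", stacklevel=2)

    knn_partners: dict[int, np.ndarray] = {}
    if partner_mode == "knn":
        # parents are always clean minority rows (danger is a subset)
        k = min(k_partner, len(clean_minority) - 1)
        pos = {int(r): i for i, r in enumerate(clean_minority)}
        nt = compute_neighbors(
            data.X[clean_minority], data.X[parents_pool], k, metric=metric,
            self_indices=np.array([pos[int(p)] for p in parents_pool]))
        for row, p in enumerate(parents_pool):
            knn_partners[int(p)] = clean_minority[nt.indices[row]]

    X_new = np.empty((n_new, data.n_features))
    prov: list[SyntheticProvenance] = []
    for i in range(n_new):
        p = int(parents_pool[rng.integers(len(parents_pool))])
        if partner_mode == "knn":
            cands = knn_partners[p]
        else:
            cands = clean_minority[clean_minority != p]
        q = int(cands[rng.integers(len(cands))])
        delta = float(rng.uniform())
        X_new[i] = data.X[p] + delta * (data.X[q] - data.X[p])
        prov.append(SyntheticProvenance(p, q, delta))
    return X_new, prov


# ---------------------------------------------------------------------------
# result assembly shared by all resamplers
# ---------------------------------------------------------------------------

def _n_new_for_target(n_clean_minority: int, n_majority: int,
                      target_ratio: float) -> int:
    return max(0, round(target_ratio * n_majority) - n_clean_minority)


def _assemble(data: LabeledDataset, drop: np.ndarray, X_synth: np.ndarray,
              prov: list[SyntheticProvenance], noise: np.ndarray,
              danger: np.ndarray) -> ResampleResult:
    keep = np.setdiff1d(np.arange(data.n_samples), np.asarray(drop, int))
    n_synth = len(X_synth)
    X = np.vstack([data.X[keep], X_synth]) if n_synth else data.X[keep]
    y = np.concatenate([data.y[keep], np.ones(n_synth, int)])
    return ResampleResult(dataset=LabeledDataset(X, y), n_synth=n_synth,
                          noise_indices=np.asarray(noise, int),
                          danger_indices=np.asarray(danger, int),
                          provenance=prov, kept_indices=keep)


def _passthrough(data: LabeledDataset, reason: str) -> ResampleResult:
    warnings.warn(f"resampler no-op: {reason}", stacklevel=3)
    return _assemble(data, np.empty(0, int), data.X[:0], [],
                     np.empty(0, int), np.empty(0, int))


def _guard(data: LabeledDataset, cfg: ResampleConfig) -> ResampleResult | None:
    """Common no-op conditions: inverted imbalance or already at target."""
    _check_two_classes(data)
    n_min = len(data.minority_indices)
    n_maj = len(data.majority_indices)
    if n_min > n_maj:
        return _passthrough(data, "minority count exceeds majority count")
    if _n_new_for_target(n_min, n_maj, cfg.target_ratio) == 0:
        return _passthrough(data, "dataset already at or above target ratio")
    return None


# ---------------------------------------------------------------------------
# the five resamplers
# ---------------------------------------------------------------------------

def bnnsmote(data: LabeledDataset, cfg: ResampleConfig = ResampleConfig()
             ) -> ResampleResult:
    """Boundary-nearest-neighbour SMOTE.

    Three steps: remove noise minority rows; identify boundary majority
    rows and the clean minority rows adjacent to them (the hard-to-learn
    set); synthesize new minority rows by interpolating each hard parent
    toward a randomly chosen clean minority row.  The output minority
    count is ``round(target_ratio * n_majority)`` (noise rows are dropped
    unless ``cfg.keep_noise``).
    """
    guard = _guard(data, cfg)
    if guard is not None:
        return guard
    rng = np.random.default_rng(cfg.seed)
    clean, noise = filter_noise(data, cfg.k_noise, cfg.metric)
    if len(clean) < 2:
        raise ResamplerError("fewer than two clean minority samples remain "
                             "after noise filtering")
    bmaj = boundary_majority(data, clean, cfg.k_boundary, cfg.metric,
                             noise=noise)
    danger = danger_minority(data, clean, bmaj, cfg.k_danger, cfg.metric,
                             noise=noise)
    n_new = _n_new_for_target(len(clean), len(data.majority_indices),
                              cfg.target_ratio)
    X_synth, prov = synthesize_samples(
        data, danger, clean, n_new, rng, partner_mode=cfg.partner_mode,
        k_partner=cfg.k_danger, metric=cfg.metric)
    drop = np.empty(0, int) if cfg.keep_noise else noise
    return _assemble(data, drop, X_synth, prov, noise, danger)


def ros(data: LabeledDataset, cfg: ResampleConfig = ResampleConfig()
        ) -> ResampleResult:
    """Random oversampling: copy minority rows uniformly with replacement."""
    guard = _guard(data, cfg)
    if guard is not None:
        return guard
    rng = np.random.default_rng(cfg.seed)
    mino = data.minority_indices
    n_new = _n_new_for_target(len(mino), len(data.majority_indices),
                              cfg.target_ratio)
    picks = mino[rng.integers(len(mino), size=n_new)]
    prov = [SyntheticProvenance(int(p), int(p), 0.0) for p in picks]
    return _assemble(data, np.empty(0, int), data.X[picks], prov,
                     np.empty(0, int), np.empty(0, int))


def smote(data: LabeledDataset, cfg: ResampleConfig = ResampleConfig()
          ) -> ResampleResult:
    """Classic SMOTE: parent uniform over all minority rows, partner from
    the parent's ``k_danger`` minority-class nearest neighbours."""
    guard = _guard(data, cfg)
    if guard is not None:
        return guard
    rng = np.random.default_rng(cfg.seed)
    mino = data.minority_indices
    if len(mino) < 2:
        raise ResamplerError("SMOTE needs at least two minority samples")
    k = min(cfg.k_danger, len(mino) - 1)
    nt = compute_neighbors(data.X[mino], data.X[mino], k, metric=cfg.metric,
                           self_indices=np.arange(len(mino)))
    n_new = _n_new_for_target(len(mino), len(data.majority_indices),
                              cfg.target_ratio)
    X_new = np.empty((n_new, data.n_features))
    prov: list[SyntheticProvenance] = []
    for i in range(n_new):
        row = rng.integers(len(mino))
        p = int(mino[row])
        q = int(mino[nt.indices[row, rng.integers(k)]])
        delta = float(rng.uniform())
        X_new[i] = data.X[p] + delta * (data.X[q] - data.X[p])
        prov.append(SyntheticProvenance(p, q, delta))
    return _assemble(data, np.empty(0, int), X_new, prov,
                     np.empty(0, int), np.empty(0, int))


def blsmote(data: LabeledDataset, cfg: ResampleConfig = ResampleConfig()
            ) -> ResampleResult:
    """Borderline-SMOTE-1: parents restricted to the DANGER set (minority
    rows with m' majority neighbours, k/2 <= m' < k).  All-interior
    minority (empty DANGER) is a warned no-op."""
    guard = _guard(data, cfg)
    if guard is not None:
        return guard
    rng = np.random.default_rng(cfg.seed)
    mino = data.minority_indices
    if len(mino) < 2:
        raise ResamplerError("BLSMOTE needs at least two minority samples")
    danger = _borderline_danger(data, mino, cfg.k_danger, cfg.metric)
    if len(danger) == 0:
        return _passthrough(data, "Borderline-SMOTE DANGER set is empty")
    k = min(cfg.k_danger, len(mino) - 1)
    pos = {int(r): i for i, r in enumerate(mino)}
    nt = compute_neighbors(data.X[mino], data.X[danger], k, metric=cfg.metric,
                           self_indices=np.array([pos[int(d)] for d in danger]))
    n_new = _n_new_for_target(len(mino), len(data.majority_indices),
                              cfg.target_ratio)
    X_new = np.empty((n_new, data.n_features))
    prov: list[SyntheticProvenance] = []
    for i in range(n_new):
        row = rng.integers(len(danger))
        p = int(danger[row])
        q = int(mino[nt.indices[row, rng.integers(k)]])
        delta = float(rng.uniform())
        X_new[i] = data.X[p] + delta * (data.X[q] - data.X[p])
        prov.append(SyntheticProvenance(p, q, delta))
    return _assemble(data, np.empty(0, int), X_new, prov,
                     np.empty(0, int), danger)


def svmsmote(data: LabeledDataset, cfg: ResampleConfig = ResampleConfig()
             ) -> ResampleResult:
    """SVM-SMOTE (interpolation variant): the boundary is approximated by
    the support vectors of a soft-margin linear SVM; minority support
    vectors are the parents, partners come from their minority nearest
    neighbours."""
    from sklearn.svm import SVC

    guard = _guard(data, cfg)
    if guard is not None:
        return guard
    rng = np.random.default_rng(cfg.seed)
    mino = data.minority_indices
    if len(mino) < 2:
        raise ResamplerError("SVM-SMOTE needs at least two minority samples")
    try:
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(data.X, data.y)
    except Exception as exc:  # pragma: no cover - sklearn failure surface
        raise ResamplerError(f"SVM training failed: {exc}") from exc
    sv = clf.support_[data.y[clf.support_] == 1]
    if len(sv) == 0:
        return _passthrough(data, "no minority-class support vectors found")
    k = min(cfg.k_danger, len(mino) - 1)
    pos = {int(r): i for i, r in enumerate(mino)}
    nt = compute_neighbors(data.X[mino], data.X[sv], k, metric=cfg.metric,
                           self_indices=np.array([pos[int(s)] for s in sv]))
    n_new = _n_new_for_target(len(mino), len(data.majority_indices),
                              cfg.target_ratio)
    X_new = np.empty((n_new, data.n_features))
    prov: list[SyntheticProvenance] = []
    for i in range(n_new):
        row = rng.integers(len(sv))
        p = int(sv[row])
        q = int(mino[nt.indices[row, rng.integers(k)]])
        delta = float(rng.uniform())
        X_new[i] = data.X[p] + delta * (data.X[q] - data.X[p])
        prov.append(SyntheticProvenance(p, q, delta))
    return _assemble(data, np.empty(0, int), X_new, prov,
                     np.empty(0, int), sv)


def none_resampler(data: LabeledDataset,
                   cfg: ResampleConfig = ResampleConfig()) -> ResampleResult:
    """Identity resampler (the 'before' condition in benchmarks)."""
    return _assemble(data, np.empty(0, int), data.X[:0], [],
                     np.empty(0, int), np.empty(0, int))


RESAMPLERS = {
    "none": none_resampler,
    "ros": ros,
    "smote": smote,
    "blsmote": blsmote,
    "svmsmote": svmsmote,
    "bnnsmote": bnnsmote,
}


def resample(name: str, data: LabeledDataset,
             cfg: ResampleConfig = ResampleConfig()) -> ResampleResult:
    """Dispatch a resampler by registry name."""
    try:
        fn = RESAMPLERS[name]
    except KeyError:
        raise KeyError(f"unknown resampler {name!r}; "
                       f"choose from {sorted(RESAMPLERS)}") from None
    return fn(data, cfg)
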