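"""Hierarchical shape-space construction for dense facial landmarks.

Raw homologous landmark configurations are turned into per-segment shape
features in four steps:

1. Generalized Procrustes Analysis (GPA) removes position, orientation and
   scale by iterative superimposition on the evolving mean shape.
2. Symmetrization: each configuration and its relabeled mirror image are
   superimposed jointly; their average is the bilaterally symmetric
   component, which is the phenotype analysed throughout (asymmetry is
   deliberately discarded).
3. The RV coefficient between every pair of landmarks (each landmark being
   an individuals x 3 block of aligned coordinates) yields a similarity
   matrix that drives a recursive 2-way spectral clustering: the full face
   is split in two, each part again in two, and so on.  Level ``l`` holds
   ``2**l`` segments; a depth-5 hierarchy therefore holds 63 segments.
4. Each segment is superimposed afresh (independently of its position in
   the full face) and summarized by principal components, the number of
   which is chosen by Horn's parallel analysis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from facedna._rng import subseed, substream

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "AlignedShapeSample",
    "SegmentationTree",
    "SegmentShapeSpace",
    "generalized_procrustes",
    "symmetric_component",
    "procrustes_distance",
    "rv_coefficient",
    "rv_similarity_matrix",
    "hierarchical_segmentation",
    "parallel_analysis",
    "segment_shape_features",
    "ShapePhenotyper",
]


# --------------------------------------------------------------------------
# landmark configurations and bilateral pairing


@dataclass
class LandmarkConfiguration:
    """One individual's (or a template's) homologous 3D landmarks.

    The first coordinate axis is the sagittal (left-right) axis: reflection
    negates it.  ``pairs`` lists (left, right) landmark index pairs and
    ``midline`` the on-midline landmarks; together they must cover every
    landmark exactly once.
    """

    coordinates: np.ndarray  # (L, 3)
    landmark_ids: list[str]
    pairs: np.ndarray  # (n_pairs, 2) int
    midline: np.ndarray  # (n_mid,) int

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.midline = np.asarray(self.midline, dtype=int)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (L, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite landmark coordinates")
        L = self.coordinates.shape[0]
        if len(self.landmark_ids) != L:
            raise ValueError("landmark_ids length mismatch")
        covered = np.concatenate([self.pairs.ravel(), self.midline])
        if sorted(covered.tolist()) != list(range(L)):
            raise ValueError("pairing must cover all landmarks exactly once")

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]

    def reflection_permutation(self) -> np.ndarray:
        """Row permutation that relabels left landmarks as right and back."""
        perm = np.arange(self.n_landmarks)
        perm[self.pairs[:, 0]] = self.pairs[:, 1]
        perm[self.pairs[:, 1]] = self.pairs[:, 0]
        return perm


def reflect_shapes(shapes: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Mirror configurations across the sagittal plane and relabel sides."""
    out = np.array(shapes[..., perm, :], copy=True)
    out[..., 0] = -out[..., 0]
    return out


@dataclass
class AlignedShapeSample:
    """GPA-superimposed (optionally symmetrized) shapes.

    ``shapes`` are centered at the origin with unit centroid size;
    ``centroid_sizes`` retain the original scales.
    """

    shapes: np.ndarray  # (N, L, 3)
    centroid_sizes: np.ndarray  # (N,)
    mean_shape: np.ndarray  # (L, 3)

    @property
    def n_individuals(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]


# --------------------------------------------------------------------------
# Procrustes machinery


def _center_and_scale(shapes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(shapes, dtype=float)
    Xc = X - X.mean(axis=-2, keepdims=True)
    sizes = np.linalg.norm(Xc, axis=(-2, -1))
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate configuration with zero centroid size")
    return Xc / sizes[..., None, None], sizes


def _optimal_rotations(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batch Kabsch: proper rotations R_i minimizing ||X_i R_i - target||."""
    H = np.einsum("nla,lb->nab", shapes, target)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    U = U.copy()
    U[:, :, -1] *= d[:, None]
    return U @ Vt


def generalized_procrustes(
    shapes: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    _symmetrize: "tuple[np.ndarray] | None" = None,
) -> AlignedShapeSample:
    """Iterative GPA removing translation, rotation and scale.

    Each configuration is centered, scaled to unit centroid size, and
    rotated to the evolving mean (itself renormalized each iteration) until
    the mean stops changing.  Scaling is plain unit-centroid-size
    normalization; reflections are never allowed.

    ``_symmetrize`` (internal) holds a reflection permutation; when given,
    the mean is replaced by the average of itself and its mirror image each
    iteration, which makes the joint original+reflection superimposition of
    :func:`symmetric_component` exactly symmetric.
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("shapes must be (N, L, 3)")
    N, L, _ = X.shape
    if N < 2 or L < 3:
        raise ValueError("need at least 2 shapes of at least 3 landmarks")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates")
    Xn, sizes = _center_and_scale(X)
    sv = np.linalg.svd(Xn, compute_uv=False)
    if np.any(sv[:, 1] < 1e-10):
        raise ValueError("collinear (rank-deficient) configuration")

    mean = Xn[0]
    aligned = Xn
    for _ in range(max_iter):
        R = _optimal_rotations(Xn, mean)
        aligned = Xn @ R
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if _symmetrize is not None:
            perm = _symmetrize[0]
            new_mean = 0.5 * (new_mean + reflect_shapes(new_mean, perm))
        nrm = np.linalg.norm(new_mean)
        if nrm < 1e-12:
            raise ValueError("mean shape collapsed; degenerate input")
        new_mean = new_mean / nrm
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            break
    aligned = Xn @ _optimal_rotations(Xn, mean)
    return AlignedShapeSample(shapes=aligned, centroid_sizes=sizes, mean_shape=mean)


def symmetric_component(
    shapes: np.ndarray,
    config: LandmarkConfiguration,
    tol: float = 1e-10,
    max_iter: int = 100,
    return_asymmetry: bool = False,
):
    """Bilaterally symmetric component of each configuration.

    Every configuration is mirrored across the sagittal plane with left and
    right landmarks relabeled; originals and reflections are superimposed
    jointly (with a mirror-symmetric mean), and each individual's symmetric
    component is the average of its own aligned original and reflection.
    The result is exactly mirror-symmetric by construction.
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 3:
        raise ValueError("shapes must be (N, L, 3)")
    if X.shape[1] != config.n_landmarks:
        raise ValueError("shape/pairing landmark count mismatch")
    perm = config.reflection_permutation()
    refl = reflect_shapes(X, perm)
    both = np.concatenate([X, refl], axis=0)
    joint = generalized_procrustes(both, tol=tol, max_iter=max_iter, _symmetrize=(perm,))
    N = X.shape[0]
    A, B = joint.shapes[:N], joint.shapes[N:]
    sym = 0.5 * (A + B)
    sample = AlignedShapeSample(
        shapes=sym,
        centroid_sizes=joint.centroid_sizes[:N],
        mean_shape=joint.mean_shape,
    )
    if return_asymmetry:
        return sample, 0.5 * (A - B)
    return sample


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Both inputs are centered and scaled to unit centroid size, then ``b``'s
    optimal proper rotation onto ``a`` is applied; the Euclidean norm of the
    residual is returned.
    """
    A, _ = _center_and_scale(np.asarray(a, float)[None])
    B, _ = _center_and_scale(np.asarray(b, float)[None])
    A, B = A[0], B[0]
    R = _optimal_rotations(B[None], A)[0]
    return float(np.linalg.norm(B @ R - A))


# --------------------------------------------------------------------------
# RV coefficient and hierarchical spectral segmentation


def rv_coefficient(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """RV coefficient between two multivariate blocks (rows = individuals).

    RV = tr(S_ab S_ba) / sqrt(tr(S_aa^2) tr(S_bb^2)) with S the cross- and
    auto-scatter matrices of the column-centered blocks; lies in [0, 1] and
    equals 1 iff the blocks are linearly equivalent up to rotation/scaling.
    """
    A = np.asarray(block_a, float)
    B = np.asarray(block_b, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("blocks must share the individual axis")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    den_a = float(np.sum((A.T @ A) ** 2))
    den_b = float(np.sum((B.T @ B) ** 2))
    if den_a < 1e-30 or den_b < 1e-30:
        raise ValueError("zero-variance block: RV undefined")
    num = float(np.sum((A.T @ B) ** 2))
    return float(np.clip(num / np.sqrt(den_a * den_b), 0.0, 1.0))


def rv_similarity_matrix(shapes: np.ndarray) -> np.ndarray:
    """Landmark x landmark RV similarity over a sample of aligned shapes.

    ``shapes`` is (N, L, 3); each landmark contributes an N x 3 block of
    coordinates centered over individuals.
    """
    X = np.asarray(shapes, float)
    N, L, _ = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    Y = Xc.transpose(1, 2, 0).reshape(L * 3, N)
    C = Y @ Y.T
    B = C.reshape(L, 3, L, 3)
    num = np.einsum("iajb,iajb->ij", B, B)
    d = np.sqrt(np.diag(num))
    if np.any(d < 1e-30):
        raise ValueError("zero-variance landmark block: RV undefined")
    rv = num / np.outer(d, d)
    rv = np.clip(0.5 * (rv + rv.T), 0.0, 1.0)
    np.fill_diagonal(rv, 1.0)
    return rv


@dataclass
class SegmentationTree:
    """Hierarchical binary partition of landmarks.

    Level ``l`` partitions the landmarks into ``2**l`` segment slots; the
    children of segment ``s`` at level ``l`` are ``2s`` and ``2s + 1`` at
    level ``l + 1``.  A segment too small to split passes all its landmarks
    to its left child (the right slot stays empty), so the per-level count
    stays exactly ``2**l``.  Global segment indices are 1-based heap
    positions: the full face is segment 1, its children 2 and 3, etc.
    """

    depth: int
    labels: dict[int, np.ndarray] = field(repr=False)

    @property
    def n_landmarks(self) -> int:
        return len(self.labels[0])

    @property
    def n_segments(self) -> int:
        return 2 ** (self.depth + 1) - 1

    def segment_indices(self, level: int, seg: int) -> np.ndarray:
        return np.flatnonzero(self.labels[level] == seg)

    def iter_segments(self):
        """Yield (level, seg_id, global_index, landmark_indices)."""
        for level in range(self.depth + 1):
            for seg in range(2**level):
                yield level, seg, 2**level + seg, self.segment_indices(level, seg)

    def validate(self) -> None:
        for level in range(self.depth + 1):
            lab = self.labels[level]
            if lab.min() < 0 or lab.max() >= 2**level:
                raise ValueError(f"labels out of range at level {level}")
            if level > 0:
                if not np.array_equal(lab // 2, self.labels[level - 1]):
                    raise ValueError(f"child/parent mismatch at level {level}")

    def to_json(self, path) -> None:
        records = []
        for level, seg, gidx, idx in self.iter_segments():
            records.append(
                {
                    "level": level,
                    "segment": int(seg),
                    "index": int(gidx),
                    "parent": int(2 ** (level - 1) + seg // 2) if level > 0 else None,
                    "landmarks": [int(i) for i in idx],
                }
            )
        with open(path, "w") as fh:
            json.dump({"depth": self.depth, "segments": records}, fh)

    @classmethod
    def from_json(cls, path) -> "SegmentationTree":
        with open(path) as fh:
            data = json.load(fh)
        depth = int(data["depth"])
        n = max(max(r["landmarks"], default=-1) for r in data["segments"]) + 1
        labels = {lv: np.zeros(n, dtype=int) for lv in range(depth + 1)}
        for r in data["segments"]:
            labels[r["level"]][np.asarray(r["landmarks"], dtype=int)] = r["segment"]
        tree = cls(depth=depth, labels=labels)
        tree.validate()
        return tree


def _spectral_two_cut(W: np.ndarray, seed: int) -> np.ndarray:
    """2-way normalized spectral cut of an affinity matrix.

    Symmetric normalized Laplacian, embedding on the 2 smallest
    eigenvectors with row normalization, then k-means (10 restarts, seeded).
    """
    W = np.asarray(W, float).copy()
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        # isolated landmark: separate it from the rest deterministically
        lab = (deg <= 0).astype(int)
        return lab if lab.min() == 0 else np.zeros_like(lab)
    dinv = 1.0 / np.sqrt(deg)
    lap = np.eye(len(W)) - dinv[:, None] * W * dinv[None, :]
    lap = 0.5 * (lap + lap.T)
    _, vecs = eigh(lap, subset_by_index=[0, 1])
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms < 1e-12] = 1.0
    emb = vecs / norms[:, None]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed % (2**31 - 1))
    return km.fit_predict(emb)


def hierarchical_segmentation(
    sample: AlignedShapeSample,
    depth: int,
    seed: int,
    min_split: int = 4,
) -> SegmentationTree:
    """Recursive 2-way spectral segmentation of landmarks by RV similarity.

    At every level each current segment is (if it holds at least
    ``min_split`` landmarks) split in two by a spectral cut of the RV
    similarity matrix recomputed over that segment's landmarks only.  The
    child containing the lowest landmark index is the left child, making
    the labeling deterministic under a fixed seed.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    L = sample.n_landmarks
    if 2**depth > L:
        raise ValueError(
            f"depth {depth} needs at least {2 ** depth} landmarks, got {L}"
        )
    labels = {0: np.zeros(L, dtype=int)}
    for level in range(depth):
        cur = labels[level]
        nxt = np.empty(L, dtype=int)
        for seg in range(2**level):
            idx = np.flatnonzero(cur == seg)
            if len(idx) == 0:
                continue
            if len(idx) < min_split:
                nxt[idx] = 2 * seg
                continue
            W = rv_similarity_matrix(sample.shapes[:, idx, :])
            cut = _spectral_two_cut(W, subseed(seed, f"segcut-{level}-{seg}"))
            if cut.min() == cut.max():
                nxt[idx] = 2 * seg
                continue
            left_label = cut[0]  # cluster of the lowest landmark index
            nxt[idx[cut == left_label]] = 2 * seg
            nxt[idx[cut != left_label]] = 2 * seg + 1
        labels[level + 1] = nxt
    tree = SegmentationTree(depth=depth, labels=labels)
    tree.validate()
    return tree


# --------------------------------------------------------------------------
# parallel analysis and per-segment shape features


def parallel_analysis(
    data: np.ndarray,
    n_permutations: int = 100,
    percentile: float = 0.95,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis: how many PCs beat permuted data.

    Eigenvalues of the column-centered covariance are compared to the given
    percentile of eigenvalues obtained from data with every column
    independently permuted; PCs are retained while the observed eigenvalue
    exceeds its permuted counterpart (stopping at the first failure), and
    at least one PC is always retained.
    """
    X = np.asarray(data, float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    N, P = X.shape
    if N <= 2 or P < 1:
        raise ValueError("need N > 2 and P >= 1")
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    rng = substream(seed, "parallel-analysis")
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    ev = sv**2 / (N - 1)
    K = len(ev)
    perm_ev = np.empty((n_permutations, K))
    for b in range(n_permutations):
        order = np.argsort(rng.random((N, P)), axis=0)
        Xp = Xc[order, np.arange(P)]
        Xp -= Xp.mean(axis=0)
        sp = np.linalg.svd(Xp, compute_uv=False)
        perm_ev[b] = sp**2 / (N - 1)
    thr = np.quantile(perm_ev, percentile, axis=0)
    exceeds = ev > thr
    retained = int(np.argmin(exceeds)) if not exceeds.all() else K
    return max(retained, 1)


@dataclass
class SegmentShapeSpace:
    """PCA shape-space of one facial segment (fresh GPA, own basis)."""

    segment: int  # global 1-based heap index
    level: int
    seg_id: int
    landmarks: np.ndarray
    scores: np.ndarray  # (N, k)
    basis: np.ndarray  # (k, 3*L_seg)
    center: np.ndarray  # (3*L_seg,) PCA centering vector
    segment_mean: np.ndarray  # (L_seg, 3) GPA mean of the segment
    retained_pc_count: int
    explained_variance_fraction: float
    zero_variance: bool = False


def segment_shape_features(
    sample: AlignedShapeSample,
    tree: SegmentationTree,
    n_permutations: int = 100,
    percentile: float = 0.95,
    seed: int = 0,
    min_landmarks: int = 3,
) -> list[SegmentShapeSpace]:
    """Per-segment GPA + PCA shape features with parallel-analysis retention.

    Each segment's landmarks are superimposed afresh, independently of the
    rest of the face, and the aligned coordinates are summarized by the PCs
    retained by parallel analysis.  Segments with fewer than
    ``min_landmarks`` landmarks are skipped with a warning.
    """
    if tree.n_landmarks != sample.n_landmarks:
        raise ValueError("tree and sample landmark counts differ")
    N = sample.n_individuals
    out: list[SegmentShapeSpace] = []
    for level, seg, gidx, idx in tree.iter_segments():
        if len(idx) < min_landmarks:
            warnings.warn(
                f"segment {gidx} (level {level}) has {len(idx)} landmarks; skipped"
            )
            continue
        gpa = generalized_procrustes(sample.shapes[:, idx, :])
        flat = gpa.shapes.reshape(N, -1)
        center = flat.mean(axis=0)
        Xc = flat - center
        total_var = float(np.sum(Xc**2) / (N - 1))
        if total_var < 1e-24:
            out.append(
                SegmentShapeSpace(
                    segment=gidx, level=level, seg_id=seg, landmarks=idx,
                    scores=np.zeros((N, 1)), basis=np.zeros((1, flat.shape[1])),
                    center=center, segment_mean=gpa.mean_shape,
                    retained_pc_count=1, explained_variance_fraction=0.0,
                    zero_variance=True,
                )
            )
            continue
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        ev = s**2 / (N - 1)
        k = parallel_analysis(
            flat, n_permutations=n_permutations, percentile=percentile,
            seed=subseed(seed, f"pa-{gidx}"),
        )
        k = min(k, int(np.sum(ev > 1e-12 * ev[0])))
        k = max(k, 1)
        out.append(
            SegmentShapeSpace(
                segment=gidx, level=level, seg_id=seg, landmarks=idx,
                scores=U[:, :k] * s[:k], basis=Vt[:k], center=center,
                segment_mean=gpa.mean_shape, retained_pc_count=k,
                explained_variance_fraction=float(ev[:k].sum() / ev.sum()),
            )
        )
    return out


# --------------------------------------------------------------------------
# fit/transform facade used by the pipeline (train on one set, project any)


def _align_single(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Center, unit-scale and rotate one configuration onto ``target``."""
    X, _ = _center_and_scale(np.asarray(shape, float)[None])
    R = _optimal_rotations(X, target)[0]
    return X[0] @ R


class ShapePhenotyper:
    """Fit the full shape pipeline on one sample; project any other.

    ``fit`` symmetrizes and superimposes the training faces, segments the
    landmarks, and builds per-segment PCA bases.  ``transform`` maps new raw
    faces into the fitted spaces (symmetric component against the stored
    mean, per-segment alignment to the stored segment means, projection on
    the stored bases), so galleries and probes never influence the model.
    """

    def __init__(
        self,
        depth: int = 5,
        n_permutations: int = 100,
        percentile: float = 0.95,
        seed: int = 0,
    ) -> None:
        self.depth = depth
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.seed = seed
        self.config: LandmarkConfiguration | None = None
        self.tree: SegmentationTree | None = None
        self.spaces: list[SegmentShapeSpace] | None = None
        self.mean_shape: np.ndarray | None = None

    def fit(self, shapes: np.ndarray, config: LandmarkConfiguration) -> "ShapePhenotyper":
        self.config = config
        sample = symmetric_component(shapes, config)
        self.mean_shape = sample.mean_shape
        self.tree = hierarchical_segmentation(sample, self.depth, seed=self.seed)
        self.spaces = segment_shape_features(
            sample, self.tree, n_permutations=self.n_permutations,
            percentile=self.percentile, seed=self.seed,
        )
        return self

    def symmetrize(self, shapes: np.ndarray) -> np.ndarray:
        """Symmetric components of new faces against the fitted mean."""
        assert self.config is not None and self.mean_shape is not None
        perm = self.config.reflection_permutation()
        out = np.empty((len(shapes), self.config.n_landmarks, 3))
        for i, x in enumerate(shapes):
            a = _align_single(x, self.mean_shape)
            b = _align_single(reflect_shapes(x[None], perm)[0], self.mean_shape)
            out[i] = 0.5 * (a + b)
        return out

    def transform(self, shapes: np.ndarray) -> dict[int, np.ndarray]:
        """Project raw faces into every fitted segment space.

        Returns a mapping from global segment index to an (N, k) score
        matrix.
        """
        assert self.spaces is not None
        sym = self.symmetrize(shapes)
        scores: dict[int, np.ndarray] = {}
        for sp in self.spaces:
            sub = sym[:, sp.landmarks, :]
            flat = np.empty((len(sub), sp.basis.shape[1]))
            for i, x in enumerate(sub):
                flat[i] = _align_single(x, sp.segment_mean).ravel()
            scores[sp.segment] = (flat - sp.center) @ sp.basis.T
        return scores

    @property
    def segment_ids(self) -> list[int]:
        assert self.spaces is not None
        return [sp.segment for sp in self.spaces]
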