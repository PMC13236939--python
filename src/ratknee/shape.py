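"""Statistical shape and appearance model (SSAM) of the knee cohort.

The model concatenates, per specimen, the corresponded vertex coordinates of
femur, tibia-fibula and patella (shape block, mm) and the per-vertex
equivalent mineral densities (appearance block, g/cm^3), performs a
generalized Procrustes alignment of the shape block, and applies PCA to the
weighted, aligned vectors.  Instances are expressed as per-component scores
in SD units, constrained to +-3 SD for sampling and (by default) for fitting.

``ShapeAppearanceModel`` follows the scikit-learn estimator protocol
(``fit`` / ``transform`` / ``inverse_transform``, fitted attributes with a
trailing underscore); the module-level functions operate directly on
:class:`~ratknee.cohort.KneeSpecimen` objects and wrap the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import KneeSpecimen

BODY_ORDER = ("femur", "tibia_fibula", "patella")


class CorrespondenceError(ValueError):
    """Raised when a specimen is not on the cohort template topology."""


class AlignmentError(ValueError):
    """Raised for degenerate Procrustes alignment input."""


# ----------------------------------------------------------------------
# vectorization
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BlockLayout:
    """Offsets of the shape and appearance blocks of a concatenated vector."""

    body_vertex_counts: tuple[int, ...]

    @property
    def n_points(self) -> int:
        return int(sum(self.body_vertex_counts))

    @property
    def n_shape(self) -> int:
        return 3 * self.n_points

    @property
    def n_total(self) -> int:
        return self.n_shape + self.n_points

    @classmethod
    def from_specimen(cls, s: KneeSpecimen) -> "BlockLayout":
        return cls(tuple(s.body(b).n_vertices for b in BODY_ORDER))

    def body_point_slices(self) -> dict[str, slice]:
        out, off = {}, 0
        for body, n in zip(BODY_ORDER, self.body_vertex_counts):
            out[body] = slice(off, off + n)
            off += n
        return out


def specimen_raw_vector(s: KneeSpecimen, layout: BlockLayout | None = None) -> np.ndarray:
    """Unweighted concatenation [coords..., densities...] in template order."""
    if layout is not None and BlockLayout.from_specimen(s) != layout:
        raise CorrespondenceError("specimen is not on the cohort template topology")
    coords = np.concatenate([s.body(b).vertices.ravel() for b in BODY_ORDER])
    dens = []
    for b in BODY_ORDER:
        d = s.body(b).vertex_density
        if d is None:
            raise CorrespondenceError(f"{b}: vertex_density required for the appearance block")
        dens.append(d)
    return np.concatenate([coords, np.concatenate(dens)])


def to_shape_vector(s: KneeSpecimen, w_s: float = 1.0, w_a: float = 1.0,
                    layout: BlockLayout | None = None) -> np.ndarray:
    """Weighted shape/appearance vector; invertible given template and weights."""
    if w_s <= 0 or w_a <= 0:
        raise ValueError("block weights must be positive")
    if layout is None:
        layout = BlockLayout.from_specimen(s)
    raw = specimen_raw_vector(s, layout)
    out = raw.copy()
    out[: layout.n_shape] *= w_s
    out[layout.n_shape :] *= w_a
    return out


def from_shape_vector(vec: np.ndarray, template: KneeSpecimen, w_s: float = 1.0,
                      w_a: float = 1.0, layout: BlockLayout | None = None) -> KneeSpecimen:
    """Inverse of :func:`to_shape_vector` on the given template topology."""
    if layout is None:
        layout = BlockLayout.from_specimen(template)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (layout.n_total,):
        raise CorrespondenceError("vector length does not match the template layout")
    coords = (vec[: layout.n_shape] / w_s).reshape(layout.n_points, 3)
    dens = vec[layout.n_shape :] / w_a
    out = template.copy()
    for body, sl in layout.body_point_slices().items():
        mesh = out.body(body)
        mesh.vertices = coords[sl].copy()
        mesh.vertex_density = dens[sl].copy()
    return out


def cohort_matrix(cohort: list[KneeSpecimen]) -> tuple[np.ndarray, BlockLayout]:
    if len(cohort) < 2:
        raise ValueError("need at least 2 specimens")
    layout = BlockLayout.from_specimen(cohort[0])
    X = np.stack([specimen_raw_vector(s, layout) for s in cohort])
    return X, layout


# ----------------------------------------------------------------------
# generalized Procrustes alignment (rigid; optional uniform scale)
# ----------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||P @ R.T - Q|| for centred point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def procrustes_align(points: np.ndarray, reference: np.ndarray,
                     allow_scaling: bool = False) -> np.ndarray:
    """Rigidly align one point set to a (centred) reference."""
    c = points.mean(axis=0)
    P = points - c
    ref_c = reference - reference.mean(axis=0)
    if np.allclose(P, 0):
        raise AlignmentError("degenerate point set: all points coincident")
    R = _kabsch(P, ref_c)
    out = P @ R.T
    if allow_scaling:
        s = np.einsum("ij,ij->", out, ref_c) / np.einsum("ij,ij->", out, out)
        out = out * s
    return out + reference.mean(axis=0)


def gpa_align(point_sets: np.ndarray, allow_scaling: bool = False,
              tol: float = 1e-10, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Generalized Procrustes alignment of (n, P, 3) point sets.

    Returns (aligned point sets, mean shape).  The mean shape is centred at
    the origin; iteration stops when the mean changes by less than ``tol``
    RMS or after ``max_iter`` rounds.
    """
    X = np.asarray(point_sets, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise AlignmentError("need at least two (P, 3) point sets")
    aligned = X - X.mean(axis=1, keepdims=True)
    if np.allclose(aligned, 0):
        raise AlignmentError("degenerate cohort: all points coincident")
    mean = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(len(aligned)):
            aligned[i] = procrustes_align(aligned[i], mean, allow_scaling)
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            break
    return aligned, mean


# ----------------------------------------------------------------------
# the estimator
# ----------------------------------------------------------------------

class ShapeAppearanceModel(TransformerMixin, BaseEstimator):
    """PCA over GPA-aligned shape + appearance vectors (the SSAM).

    Parameters
    ----------
    layout : BlockLayout
        Split between the shape and appearance blocks of the input rows.
    n_components : int or None
        Retained components; ``None`` keeps every nonzero-variance component
        (at most ``n_samples - 1``).
    w_s : float
        Shape-block weight (default 1: coordinates stay in mm).
    w_a : float or "auto"
        Appearance-block weight; ``"auto"`` equalises the total variance of
        the two blocks on the training set.
    align : bool
        Run rigid GPA on the shape block before PCA.
    clip : bool
        Clamp transformed scores to ``[-limit_sd, limit_sd]``.
    """

    def __init__(self, layout: BlockLayout | None = None, n_components: int | None = None,
                 w_s: float = 1.0, w_a="auto", align: bool = True,
                 allow_scaling: bool = False, clip: bool = True, limit_sd: float = 3.0):
        self.layout = layout
        self.n_components = n_components
        self.w_s = w_s
        self.w_a = w_a
        self.align = align
        self.allow_scaling = allow_scaling
        self.clip = clip
        self.limit_sd = limit_sd

    # ------------------------------------------------------------------
    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = self.layout
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != lo.n_total:
            raise CorrespondenceError("row length does not match the block layout")
        return X[:, : lo.n_shape].reshape(len(X), lo.n_points, 3), X[:, lo.n_shape :]

    def fit(self, X: np.ndarray, y=None) -> "ShapeAppearanceModel":
        if self.layout is None:
            raise ValueError("a BlockLayout is required")
        if self.w_s <= 0:
            raise ValueError("w_s must be positive")
        if self.w_a != "auto" and self.w_a <= 0:
            raise ValueError("w_a must be positive or 'auto'")
        S, A = self._split(X)
        n = len(S)
        if n < 2:
            raise ValueError("need at least 2 training specimens")
        if self.n_components is not None and self.n_components > n - 1:
            raise ValueError("n_components must be <= n_training - 1")

        if self.align:
            S_aligned, ref = gpa_align(S, allow_scaling=self.allow_scaling)
        else:
            S_aligned, ref = S.copy(), S.mean(axis=0)
        self.alignment_ref_ = ref

        var_s = float(((S_aligned - S_aligned.mean(0)) ** 2).sum() / max(n - 1, 1))
        var_a = float(((A - A.mean(0)) ** 2).sum() / max(n - 1, 1))
        if self.w_a == "auto":
            self.w_a_ = float(np.sqrt(var_s / var_a)) if var_a > 0 and var_s > 0 else 1.0
        else:
            self.w_a_ = float(self.w_a)
        self.w_s_ = float(self.w_s)

        Y = np.hstack([self.w_s_ * S_aligned.reshape(n, -1), self.w_a_ * A])
        self.mean_ = Y.mean(axis=0)
        Yc = Y - self.mean_
        U, sv, Vt = np.linalg.svd(Yc, full_matrices=False)
        sd = sv / np.sqrt(n - 1)
        # rank cut: relative to the leading mode AND to the coordinate scale,
        # so an (all-identical) zero-variance cohort yields zero components
        tol = max(1e-10 * (sd[0] if sd.size else 0.0),
                  1e-9 * max(1.0, float(np.abs(self.mean_).max())))
        k = int((sd > tol).sum())
        k = min(k, n - 1)
        if self.n_components is not None:
            k = min(k, self.n_components)
        comps, sd = Vt[:k], sd[:k]
        # deterministic sign: largest-magnitude loading positive
        for j in range(k):
            i = np.argmax(np.abs(comps[j]))
            if comps[j, i] < 0:
                comps[j] = -comps[j]
                U[:, j] = -U[:, j]
        self.components_ = comps
        self.sd_ = sd
        self.n_components_ = k
        self.n_features_in_ = self.layout.n_total
        self.n_training_ = n
        return self

    # ------------------------------------------------------------------
    def _weighted_aligned(self, X: np.ndarray) -> np.ndarray:
        S, A = self._split(X)
        rows = []
        for i in range(len(S)):
            pts = procrustes_align(S[i], self.alignment_ref_, self.allow_scaling) if self.align else S[i]
            rows.append(np.concatenate([self.w_s_ * pts.ravel(), self.w_a_ * A[i]]))
        return np.stack(rows)

    def transform(self, X: np.ndarray, clip: bool | None = None) -> np.ndarray:
        """Project rows onto the basis; scores are in SD units."""
        check_is_fitted(self, "components_")
        Y = self._weighted_aligned(X) - self.mean_
        raw = Y @ self.components_.T
        with np.errstate(divide="ignore", invalid="ignore"):
            B = np.where(self.sd_ > 0, raw / np.where(self.sd_ == 0, 1.0, self.sd_), 0.0)
        clip = self.clip if clip is None else clip
        if clip:
            B = np.clip(B, -self.limit_sd, self.limit_sd)
        return B

    def inverse_transform(self, B: np.ndarray) -> np.ndarray:
        """Reconstruct unweighted rows (aligned frame) from SD-unit scores."""
        check_is_fitted(self, "components_")
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if B.shape[1] != self.n_components_:
            raise ValueError("score dimension does not match n_components_")
        Y = self.mean_ + (B * self.sd_) @ self.components_
        lo = self.layout
        out = Y.copy()
        out[:, : lo.n_shape] /= self.w_s_
        out[:, lo.n_shape :] /= self.w_a_
        return out

    def sample_coefficients(self, n_per_component: int = 20, limit_sd: float | None = None,
                            rng: np.random.Generator | None = None) -> np.ndarray:
        """Uniform single-mode scores in [-limit_sd, limit_sd], 20 per component."""
        check_is_fitted(self, "components_")
        if rng is None:
            rng = np.random.default_rng()
        lim = self.limit_sd if limit_sd is None else limit_sd
        k = self.n_components_
        B = np.zeros((k * n_per_component, k))
        for j in range(k):
            B[j * n_per_component : (j + 1) * n_per_component, j] = rng.uniform(-lim, lim, n_per_component)
        return B

    @property
    def total_variance_(self) -> float:
        return float((self.sd_**2).sum())


# ----------------------------------------------------------------------
# specimen-level wrappers
# ----------------------------------------------------------------------

@dataclass
class SSAModelBundle:
    """Fitted estimator plus the template needed to rebuild specimens."""

    model: ShapeAppearanceModel
    template: KneeSpecimen
    layout: BlockLayout

    @property
    def n_components(self) -> int:
        return self.model.n_components_

    @property
    def sd(self) -> np.ndarray:
        return self.model.sd_


def build_ssam(training: list[KneeSpecimen], w_s: float = 1.0, w_a="auto",
               n_components: int | None = None, align: bool = True,
               clip: bool = True) -> SSAModelBundle:
    """Fit the SSAM on a training cohort sharing one template topology."""
    X, layout = cohort_matrix(training)
    model = ShapeAppearanceModel(layout=layout, n_components=n_components, w_s=w_s,
                                 w_a=w_a, align=align, clip=clip)
    model.fit(X)
    return SSAModelBundle(model=model, template=training[0].copy(), layout=layout)


def fit_coefficients(bundle: SSAModelBundle, target: KneeSpecimen,
                     clip: bool = True) -> np.ndarray:
    """Least-squares scores (SD units) of a target specimen; optionally clipped."""
    x = specimen_raw_vector(target, bundle.layout)
    return bundle.model.transform(x[None, :], clip=clip)[0]


def reconstruct_specimen(bundle: SSAModelBundle, b: np.ndarray) -> KneeSpecimen:
    """Mean + sum_i b_i sd_i c_i, de-vectorized to a specimen.

    Landmarks and ligament attachments ride along with their marker vertices.
    """
    row = bundle.model.inverse_transform(np.asarray(b, dtype=float)[None, :])[0]
    return from_shape_vector(row, bundle.template, 1.0, 1.0, bundle.layout)


def sample_ssam(bundle: SSAModelBundle, n_per_component: int = 20, limit_sd: float = 3.0,
                seed: int | np.random.Generator = 0) -> list[KneeSpecimen]:
    """20 uniform resamples within +-3 SD along each retained component."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = bundle.model.sample_coefficients(n_per_component, limit_sd, rng)
    return [reconstruct_specimen(bundle, b) for b in B]


# ----------------------------------------------------------------------
# leave-one-out geometric validation
# ----------------------------------------------------------------------

@dataclass
class GeomError:
    """Surface error (mm) between a predicted and a target specimen."""

    rms: float
    max: float
    per_body: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.rms <= self.max + 1e-12:
            raise ValueError("require 0 <= rms <= max")


def geometric_error(predicted: KneeSpecimen, target_aligned_points: np.ndarray,
                    layout: BlockLayout) -> GeomError:
    pred = np.vstack([predicted.body(b).vertices for b in BODY_ORDER])
    d = np.linalg.norm(pred - target_aligned_points, axis=1)
    per_body = {b: float(np.sqrt(np.mean(d[sl] ** 2)))
                for b, sl in layout.body_point_slices().items()}
    return GeomError(rms=float(np.sqrt(np.mean(d**2))), max=float(d.max()), per_body=per_body)


def loo_validate(cohort: list[KneeSpecimen], w_s: float = 1.0, w_a="auto",
                 n_components: int | None = None, clip: bool = False,
                 include_contralateral: bool = True
                 ) -> tuple[pd.DataFrame, list[KneeSpecimen]]:
    """Limb-level leave-one-out: predict each limb from the remaining limbs.

    Fitting defaults to the unclipped least-squares projection: on a
    bilateral cohort the within-animal modes carry tiny variance, so a
    left-out limb's SD-normalised score along them is routinely far beyond
    3 SD and clipping would bias the validation; the +-3 SD constraint
    remains in force for generative sampling.

    The contralateral limb of the target animal is retained in the training
    set by default, matching the study design.  Returns one record per limb
    (rms/max surface error in mm, per-body breakdown, and the RMS distance of
    the target to the training mean shape as a baseline) plus the predicted
    specimens.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 limbs")
    records, predicted_all = [], []
    for i, target in enumerate(cohort):
        training = [s for j, s in enumerate(cohort)
                    if j != i and (include_contralateral or s.animal_id != target.animal_id)]
        bundle = build_ssam(training, w_s=w_s, w_a=w_a, n_components=n_components, clip=clip)
        b = fit_coefficients(bundle, target, clip=clip)
        pred = reconstruct_specimen(bundle, b)
        # the target, aligned into the model frame, is the comparison reference
        x = specimen_raw_vector(target, bundle.layout)
        S, _ = bundle.model._split(x[None, :])
        tgt_aligned = procrustes_align(S[0], bundle.model.alignment_ref_)
        err = geometric_error(pred, tgt_aligned, bundle.layout)
        baseline = float(np.sqrt(np.mean(
            np.linalg.norm(tgt_aligned - bundle.model.alignment_ref_, axis=1) ** 2)))
        records.append({
            "limb": i,
            "animal_id": target.animal_id,
            "side": target.side_as_acquired,
            "rms_mm": err.rms,
            "max_mm": err.max,
            **{f"rms_{b_}_mm": v for b_, v in err.per_body.items()},
            "baseline_rms_mm": baseline,
            "n_components": bundle.n_components,
        })
        predicted_all.append(pred)
    return pd.DataFrame(records), predicted_all


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def save_ssam(bundle: SSAModelBundle, path) -> None:
    """NPZ archive of mean, basis, SDs, weights and template reference."""
    m = bundle.model
    np.savez_compressed(
        path,
        mean=m.mean_, components=m.components_, sd=m.sd_,
        w_s=m.w_s_, w_a=m.w_a_,
        alignment_ref=m.alignment_ref_,
        body_vertex_counts=np.asarray(bundle.layout.body_vertex_counts),
    )
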