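"""Eigenface basis learning and eigenspace projection.

The classifier's features are the projection weights of delta-images
onto a principal-component (eigenface) basis fitted to a training
database.  Training rows are zero-meaned; when the number of images n is
smaller than the pixel count p (the usual case), the decomposition is
computed from the n x n Gram ("snapshot") matrix, which shares the
nonzero spectrum of the p x p covariance.  Eigenvectors are unit
normalized and components whose eigenvalue falls below a threshold
(default 1e-6, on native-intensity-scale data with the unbiased 1/(n-1)
covariance normalization) are eliminated.

The subspace dimensionality N is chosen as the smallest number of
leading components whose cumulative explained-variance ratio reaches the
``pc_expl_var`` percentage, computed over the retained components.

Eigenvector signs are arbitrary; each component's largest-magnitude
element is made positive so serialized models are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import Region
from .preprocess import ImageDatabase

DEFAULT_EIGENVALUE_THRESHOLD = 1e-6


@dataclass
class EigenModel:
    mean_vector: np.ndarray  # (p,)
    components: np.ndarray  # (m, p), unit-norm rows, descending eigenvalue
    eigenvalues: np.ndarray  # (m,), descending
    region: Optional[Region] = None
    roi_shape: Optional[tuple[int, int]] = None
    eigenvalue_threshold: float = DEFAULT_EIGENVALUE_THRESHOLD

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def explained_ratio(self) -> np.ndarray:
        """Eigenvalues normalized to sum 1 over the retained components."""
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass(frozen=True)
class ProjectedFeatures:
    weights: np.ndarray  # (n, N)

    @property
    def component_count(self) -> int:
        return self.weights.shape[1]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(len(components)), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_eigenfaces(
    db: ImageDatabase | np.ndarray,
    eigenvalue_threshold: float = DEFAULT_EIGENVALUE_THRESHOLD,
) -> EigenModel:
    """Fit an eigenface model to the rows of a (delta-image) database.

    Accepts an :class:`ImageDatabase` or a bare (n, p) matrix.  Raises on
    n < 2 and when every eigenvalue falls below the threshold (e.g. a
    database of identical images).
    """
    if isinstance(db, ImageDatabase):
        X = db.matrix
        region, roi_shape = db.region, db.roi_shape
    else:
        X = np.asarray(db, dtype=float)
        region, roi_shape = None, None
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 images to fit eigenfaces, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    if n < p:
        # snapshot method: eigendecompose the n x n Gram matrix
        gram = (Xc @ Xc.T) / (n - 1)
        vals, vecs = np.linalg.eigh(gram)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals >= eigenvalue_threshold
        vals, vecs = vals[keep], vecs[:, keep]
        if vals.size == 0:
            raise ValueError(
                "all eigenvalues below threshold; database is degenerate"
            )
        comps = Xc.T @ vecs  # (p, m), unnormalized
        comps /= np.linalg.norm(comps, axis=0)
        comps = comps.T
    else:
        cov = (Xc.T @ Xc) / (n - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals >= eigenvalue_threshold
        vals, vecs = vals[keep], vecs[:, keep]
        if vals.size == 0:
            raise ValueError(
                "all eigenvalues below threshold; database is degenerate"
            )
        comps = vecs.T
    return EigenModel(
        mean_vector=mean,
        components=_fix_signs(comps),
        eigenvalues=vals,
        region=region,
        roi_shape=roi_shape,
        eigenvalue_threshold=eigenvalue_threshold,
    )


def select_num_components(model: EigenModel, pc_expl_var: float) -> int:
    """Smallest N whose cumulative explained ratio reaches pc_expl_var %."""
    if not (0.0 < pc_expl_var <= 100.0):
        raise ValueError(f"pc_expl_var must be in (0, 100], got {pc_expl_var}")
    cum = np.cumsum(model.explained_ratio)
    target = pc_expl_var / 100.0 - 1e-12  # guard float round-off at 100%
    return int(np.searchsorted(cum, target) + 1)


def project(
    model: EigenModel, images: np.ndarray, n_components: Optional[int] = None
) -> ProjectedFeatures:
    """Project image rows onto the first N eigenfaces."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    N = model.n_components if n_components is None else int(n_components)
    if N > model.n_components:
        raise ValueError(
            f"requested {N} components, model has {model.n_components}"
        )
    if images.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"image length {images.shape[1]} != model dimensionality "
            f"{model.mean_vector.shape[0]}"
        )
    return ProjectedFeatures((images - model.mean_vector) @ model.components[:N].T)


def reconstruct(model: EigenModel, features: ProjectedFeatures) -> np.ndarray:
    """Mean image plus the weighted component combination."""
    N = features.component_count
    if N > model.n_components:
        raise ValueError(
            f"feature width {N} exceeds model components {model.n_components}"
        )
    return model.mean_vector + features.weights @ model.components[:N]


def eigenface_sweep(
    model: EigenModel,
    pc_index: int,
    training_features: ProjectedFeatures,
    sd_steps: Optional[np.ndarray] = None,
) -> list[np.ndarray]:
    """Visualize what one eigenface encodes (a component sweep).

    For each step s the weight mean + s*SD (over the training features of
    that component) is applied to the component and added to the mean
    image.  ``pc_index`` is 1-based; default steps are -3..+3 SD.
    """
    if not (1 <= pc_index <= model.n_components):
        raise ValueError(f"pc_index {pc_index} out of range")
    if sd_steps is None:
        sd_steps = np.arange(-3.0, 3.0 + 1e-9, 1.0)
    if pc_index > training_features.component_count:
        raise ValueError("training features do not cover the requested PC")
    w = training_features.weights[:, pc_index - 1]
    mean_w = float(w.mean())
    sd_w = float(w.std(ddof=1)) if w.size > 1 else 0.0
    comp = model.components[pc_index - 1]
    shape = model.roi_shape
    out = []
    for s in np.asarray(sd_steps, dtype=float):
        img = model.mean_vector + (mean_w + s * sd_w) * comp
        out.append(img.reshape(shape) if shape is not None else img)
    return out


def save_model(model: EigenModel, prefix: str | Path) -> None:  # noqa: F821
    from pathlib import Path as _P

    prefix = _P(prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        mean_vector=model.mean_vector,
        components=model.components,
        eigenvalues=model.eigenvalues,
    )
    header = {
        "region": model.region.value if model.region else "",
        "roi_shape": ",".join(map(str, model.roi_shape or ())),
        "threshold": repr(model.eigenvalue_threshold),
    }
    prefix.with_suffix(".txt").write_text(
        "".join(f"{k}: {v}\n" for k, v in header.items())
    )


def load_model(prefix: str | Path) -> EigenModel:  # noqa: F821
    from pathlib import Path as _P

    prefix = _P(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    header: dict[str, str] = {}
    for line in prefix.with_suffix(".txt").read_text().splitlines():
        k, _, v = line.partition(":")
        header[k.strip()] = v.strip()
    roi_shape = None
    if header.get("roi_shape"):
        roi_shape = tuple(int(v) for v in header["roi_shape"].split(","))
    return EigenModel(
        mean_vector=arrays["mean_vector"],
        components=arrays["components"],
        eigenvalues=arrays["eigenvalues"],
        region=Region(header["region"]) if header.get("region") else None,
        roi_shape=roi_shape,  # type: ignore[arg-type]
        eigenvalue_threshold=float(header.get("threshold", "1e-6")),
    )
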