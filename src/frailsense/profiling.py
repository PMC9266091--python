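"""Subject profiling: 24-feature fusion and 2-D embedding for decision support.

Each subject's robot-side measurements are fused into one 24-dimensional
profile — the 9 right-foot gait features, the 13 camera posture features and
the two grip maxima — and the cohort matrix is embedded in the plane with
two complementary reductions:

* exact t-SNE with Euclidean distances (local-similarity preserving), and
* non-classical MDS minimising Sammon's stress

  .. math::

     E = \\frac{1}{\\sum_{i<j} \\delta_{ij}}
         \\sum_{i<j} \\frac{(\\delta_{ij} - d_{ij})^2}{\\delta_{ij}}

  where :math:`\\delta` are the input-space and :math:`d` the embedded
  pairwise distances.  The final stress (reported as a percentage) measures
  the residual distance distortion of the map.

Because the features mix units (seconds, pixels, newtons), columns are
z-score standardized before any distance computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .grip import GripFeatures
from .imu_gait import GaitFeatures, gait_feature_names
from .posture import POSTURE_FEATURE_NAMES, PostureFeatures

__all__ = [
    "SubjectProfile",
    "Embedding2D",
    "PROFILE_FEATURE_NAMES",
    "build_profile_matrix",
    "tsne_embed",
    "sammon_embed",
    "sammon_stress",
    "profile_report",
]

#: Fixed 24-column order of the fused profile: 9 right-foot gait features,
#: 13 posture features, 2 grip maxima.
PROFILE_FEATURE_NAMES = tuple(
    gait_feature_names("right") + list(POSTURE_FEATURE_NAMES) + ["MFR", "MFL"]
)


@dataclass
class SubjectProfile:
    """One subject's fused feature set with a display-only group label."""

    subject_id: str
    gait: GaitFeatures | None
    posture: PostureFeatures | None
    grip: GripFeatures | None
    group: str = "walks-alone"  # or "walker"

    def feature_vector(self) -> pd.Series:
        for name, part in (("gait", self.gait), ("posture", self.posture), ("grip", self.grip)):
            if part is None:
                raise ValueError(f"subject {self.subject_id}: missing {name} features")
        vec = pd.concat([self.gait.right, self.posture.to_series(), self.grip.to_series()])
        vec.index = list(PROFILE_FEATURE_NAMES)
        vec.name = self.subject_id
        return vec


@dataclass
class Embedding2D:
    """Planar coordinates of a cohort plus the reduction's quality metrics."""

    coords: np.ndarray  # (n_subjects, 2)
    method: str
    subject_ids: list[str] = field(default_factory=list)
    stress: float | None = None  # Sammon stress, as a fraction
    seed: int | None = None
    stress_history: np.ndarray | None = None

    @property
    def stress_percent(self) -> float | None:
        return None if self.stress is None else 100.0 * self.stress

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["x", "y"])
        df.insert(0, "subject_id", self.subject_ids or range(len(df)))
        df["method"] = self.method
        df["stress_percent"] = np.nan if self.stress is None else self.stress_percent
        return df


def build_profile_matrix(
    profiles: list[SubjectProfile], *, standardize: bool = True
) -> pd.DataFrame:
    """Assemble the n_subjects x 24 profile matrix (z-scored by default).

    Constant columns standardize to zero rather than dividing by zero.
    """
    if not profiles:
        raise ValueError("no subjects")
    mat = pd.DataFrame([p.feature_vector() for p in profiles])
    if mat.isna().any().any():
        bad = mat.columns[mat.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in columns {bad}")
    if standardize:
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        sd = sd.where(sd > 0, 1.0)
        mat = (mat - mu) / sd
    return mat


def tsne_embed(
    matrix: pd.DataFrame | np.ndarray, perplexity: float = 3.0, seed: int = 0
) -> Embedding2D:
    """Exact t-SNE (Euclidean distances) to 2-D; deterministic per seed."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n_subjects {n}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="exact",
        metric="euclidean",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else []
    return Embedding2D(coords=coords, method="tsne", subject_ids=[str(i) for i in ids], seed=seed)


def sammon_stress(delta: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress of an embedding given condensed input distances."""
    d = pdist(coords)
    return float(np.sum((delta - d) ** 2 / delta) / np.sum(delta))


def _classical_scaling(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:ndim]
    w_pos = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_pos)


def sammon_embed(
    matrix: pd.DataFrame | np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-12,
    eps: float = 1e-9,
) -> Embedding2D:
    """Non-classical MDS under Sammon's stress criterion.

    Starts from the classical-scaling (PCoA) configuration and descends the
    stress gradient with a backtracking line search, so the stress sequence
    is non-increasing by construction.  Coincident input points are jittered
    by ``eps`` in the distance domain to keep the stress denominators
    finite.  If the iteration budget is exhausted before the relative
    improvement drops below ``tol``, the best configuration found is
    returned with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    delta = pdist(X)
    delta = np.maximum(delta, eps)
    c = np.sum(delta)
    D_in = squareform(delta)

    Y = _classical_scaling(D_in)
    stress = sammon_stress(delta, Y)
    history = [stress]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        d = np.maximum(pdist(Y), 1e-300)
        Dm = squareform(d)
        # gradient of E wrt Y
        ratio = (squareform(delta) - Dm) / (squareform(delta) * Dm + np.eye(n))
        np.fill_diagonal(ratio, 0.0)
        grad = np.zeros_like(Y)
        for k in range(2):
            diff = Y[:, k][:, None] - Y[:, k][None, :]
            grad[:, k] = (-2.0 / c) * np.sum(ratio * diff, axis=1)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            converged = True
            break
        # backtracking line search: never accept an increase
        accepted = False
        trial_step = step * 2.0
        for _ in range(40):
            Y_new = Y - trial_step * grad
            s_new = sammon_stress(delta, Y_new)
            if s_new <= stress:
                accepted = True
                break
            trial_step *= 0.5
        if not accepted:
            converged = True
            break
        improvement = stress - s_new
        Y, stress, step = Y_new, s_new, trial_step
        history.append(stress)
        if improvement <= tol * max(stress, 1e-30):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Sammon mapping did not converge in {max_iter} iterations; "
            "returning best configuration found",
            stacklevel=2,
        )
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else []
    return Embedding2D(
        coords=Y,
        method="sammon",
        subject_ids=[str(i) for i in ids],
        stress=stress,
        stress_history=np.asarray(history),
    )


def profile_report(
    embeddings: list[Embedding2D],
    labels: list[str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write scatter plots and a coordinates CSV for the cohort embeddings.

    ``labels`` gives one group label per subject ("walker" subjects are
    drawn as filled circles, "walks-alone" as stars, mirroring the clinical
    display).  Returns the written file paths keyed by artifact name.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frames = []
    for emb in embeddings:
        df = emb.to_frame()
        df["group"] = labels
        frames.append(df)

        fig, ax = plt.subplots(figsize=(5, 4))
        for group, marker, color in (("walker", "o", "tab:blue"), ("walks-alone", "*", "tab:red")):
            sel = df["group"] == group
            ax.scatter(
                df.loc[sel, "x"], df.loc[sel, "y"], marker=marker, s=80,
                color=color, label=group,
            )
        title = emb.method
        if emb.stress_percent is not None:
            title += f" (stress {emb.stress_percent:.2f}%)"
        ax.set_title(title)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
        ax.legend()
        fig.tight_layout()
        path = outdir / f"embedding_{emb.method}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"figure_{emb.method}"] = path

    csv_path = outdir / "embeddings.csv"
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    written["coordinates"] = csv_path
    return written
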