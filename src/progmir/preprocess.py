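"""Per-dataset normalization and quality control.

Each dataset is z-normalized per feature (mean 0, sample sd 1 within the
dataset) so that studies from different platforms and compartments land
on a common scale before meta-analysis.  Technical outlier samples are
flagged from inter-array mean absolute expression distances with a Tukey
fence, and a study in which more than 10% of samples are flagged is
marked for rejection.  PCA provides the unsupervised structure check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .study import ExpressionStudy

logger = logging.getLogger(__name__)


def z_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Scale every feature row to mean 0 and sample sd 1 within the dataset.

    Zero-variance features cannot be scaled and are dropped with a logged
    warning.
    """
    vals = study.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(vals.index[~keep])
        logger.warning("z_normalize: dropping %d zero-variance feature(s): %s",
                       len(dropped), dropped[:5])
    vals = vals.loc[keep]
    centered = vals.sub(vals.mean(axis=1), axis=0)
    z = centered.div(sd[keep], axis=0)
    return ExpressionStudy(values=z, annotations=study.annotations.copy(),
                           dataset_id=study.dataset_id)


@dataclass
class OutlierResult:
    """Flagged samples plus the study-level rejection verdict."""

    flagged: list
    mean_distance: pd.Series
    threshold: float
    reject_study: bool


def detect_outliers(study: ExpressionStudy, frac_threshold: float = 0.10) -> OutlierResult:
    """Flag technical outliers from inter-array mean absolute distances.

    ``D(a, b)`` is the mean over features of ``|x_fa - x_fb|``. A sample is
    an outlier when its mean distance to all other samples exceeds
    ``Q3 + 1.5 IQR`` of the per-sample mean-distance distribution; the study
    is rejected when more than ``frac_threshold`` of samples are outliers.
    """
    x = study.matrix()
    n = x.shape[1]
    if n < 3:
        raise ValueError("outlier detection needs >= 3 samples")
    # pairwise mean |difference| across features, excluding self distance
    dist = np.mean(np.abs(x[:, :, None] - x[:, None, :]), axis=0)
    mean_dist = dist.sum(axis=1) / (n - 1)
    q1, q3 = np.percentile(mean_dist, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    flagged_mask = mean_dist > fence
    flagged = [s for s, f in zip(study.sample_ids, flagged_mask) if f]
    reject = len(flagged) > frac_threshold * n
    if reject:
        logger.warning("study %s rejected: %d/%d samples flagged as outliers",
                       study.dataset_id or "<unnamed>", len(flagged), n)
    return OutlierResult(flagged=flagged,
                         mean_distance=pd.Series(mean_dist, index=study.sample_ids),
                         threshold=float(fence), reject_study=reject)


@dataclass
class PcaResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = self.variance_explained
        if np.any(np.diff(ve) > 1e-12) or ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must be non-increasing, sum <= 1")


def pca(study: ExpressionStudy, n_components: int) -> PcaResult:
    """Project samples onto the leading principal components.

    Samples are the observations; features are centered. Scores satisfy
    ``scores = centered_data.T @ loadings``.
    """
    n_feat, n_samp = study.values.shape
    if not 1 <= n_components <= min(n_feat, n_samp):
        raise ValueError("n_components must be in [1, min(features, samples)]")
    x = study.matrix().T  # samples x features
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    comp_ids = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=study.sample_ids, columns=comp_ids),
        loadings=pd.DataFrame(model.components_.T, index=study.feature_ids,
                              columns=comp_ids),
        variance_explained=model.explained_variance_ratio_.copy(),
    )
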