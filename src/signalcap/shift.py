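"""Distribution-shift analysis of snapshot (cytometry-style) marker data.

Raw intensities are arcsinh-transformed (cofactor 5, the mass-cytometry
convention) and each condition's per-marker distribution is scored against a
reference condition with the 1-D earth mover's distance (Wasserstein-1).
The resulting condition × marker EMD matrix can be embedded in 2-D through a
pluggable backend (PHATE when installed, classical MDS otherwise), and
responder fractions are quantified against a percentile threshold of the
reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .errors import ConfigurationError, NumericalError
from .types import SnapshotSample

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0


def arcsinh_transform(values, cofactor: float = DEFAULT_COFACTOR):
    """Variance-stabilizing transform ``asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ConfigurationError(f"cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def emd_score(sample, reference, signed: bool = False) -> float:
    """1-D Wasserstein-1 distance between two empirical samples.

    Inputs are expected on the transformed scale.  ``signed=True`` attaches
    the sign of the median shift (sample − reference), a convention used to
    indicate the direction of a marker response.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.size == 0 or reference.size == 0:
        raise NumericalError("EMD undefined for an empty sample")
    score = float(wasserstein_distance(sample, reference))
    if signed:
        score *= np.sign(np.median(sample) - np.median(reference)) or 1.0
    return score


def emd_matrix(
    snapshots: list[SnapshotSample],
    reference_condition: str,
    markers: list[str] | None = None,
    cofactor: float = DEFAULT_COFACTOR,
    signed: bool = False,
    transform: bool = True,
) -> pd.DataFrame:
    """Condition × marker EMD scores against the reference condition.

    ``reference_condition`` is matched against each sample's label (see
    :meth:`SnapshotSample.label`).  Scores are computed on
    arcsinh-transformed intensities unless ``transform=False``.
    """
    labels = [s.label() for s in snapshots]
    try:
        ref = snapshots[labels.index(reference_condition)]
    except ValueError:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not found; "
            f"available: {labels}"
        ) from None
    if markers is None:
        markers = ref.markers
    rows = {}
    for label, snap in zip(labels, snapshots):
        scores = []
        for marker in markers:
            if marker not in snap.marker_values.columns:
                raise ConfigurationError(
                    f"condition {label!r} is missing marker {marker!r}"
                )
            a = snap.marker_values[marker].to_numpy()
            b = ref.marker_values[marker].to_numpy()
            if transform:
                a = arcsinh_transform(a, cofactor)
                b = arcsinh_transform(b, cofactor)
            scores.append(emd_score(a, b, signed=signed))
        rows[label] = scores
    return pd.DataFrame.from_dict(rows, orient="index", columns=markers)


def embed_emd(
    matrix: pd.DataFrame,
    backend: str = "phate",
    n_components: int = 2,
    seed: int = 0,
    knn: int = 5,
) -> pd.DataFrame:
    """2-D embedding of conditions from their EMD score rows.

    Delegates to PHATE when requested and importable; otherwise falls back to
    classical metric MDS on the euclidean distances between rows (with a
    logged warning when the fallback replaces a requested backend).
    Deterministic under a fixed seed.
    """
    if matrix.isna().any().any():
        raise ConfigurationError("EMD matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    index = matrix.index
    if X.shape[0] == 1:
        coords = np.zeros((1, n_components))
        return pd.DataFrame(coords, index=index, columns=["dim1", "dim2"][:n_components])
    if backend == "phate":
        try:
            import phate  # type: ignore

            op = phate.PHATE(
                n_components=n_components,
                random_state=seed,
                knn=min(knn, X.shape[0] - 1),
                verbose=False,
            )
            coords = op.fit_transform(X)
            return pd.DataFrame(
                coords, index=index, columns=[f"dim{i+1}" for i in range(n_components)]
            )
        except ImportError:
            logger.warning("PHATE backend unavailable; falling back to MDS")
    elif backend != "mds":
        raise ConfigurationError(f"unknown embedding backend {backend!r}")
    from sklearn.manifold import MDS
    from sklearn.metrics import pairwise_distances

    dist = pairwise_distances(X)
    mds = MDS(
        n_components=n_components,
        metric="precomputed",
        init="random",
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(dist)
    return pd.DataFrame(
        coords, index=index, columns=[f"dim{i+1}" for i in range(n_components)]
    )


@dataclass
class ThresholdReport:
    """Responder fractions above a reference percentile threshold."""

    fractions: pd.Series  # per-condition fraction in [0, 1]
    threshold: float
    reference: str
    q: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "reference": self.reference,
            "q": self.q,
            "fractions": {str(k): float(v) for k, v in self.fractions.items()},
        }


def threshold_fraction(sample, reference, q: float = 95.0) -> float:
    """Fraction of sample values strictly above the reference's q-th percentile.

    The percentile uses linear interpolation between order statistics.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.size == 0:
        raise NumericalError("empty sample")
    if reference.size == 0:
        raise NumericalError("empty reference")
    if not 0 < q < 100:
        raise ConfigurationError("q must be in (0, 100)")
    cut = np.percentile(reference, q)
    return float(np.mean(sample > cut))


def threshold_report(
    snapshots: list[SnapshotSample],
    marker: str,
    reference_condition: str,
    q: float = 95.0,
    cofactor: float = DEFAULT_COFACTOR,
    transform: bool = True,
) -> ThresholdReport:
    """Per-condition responder fractions for one marker."""
    labels = [s.label() for s in snapshots]
    try:
        ref = snapshots[labels.index(reference_condition)]
    except ValueError:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} not found"
        ) from None

    def marker_values(snap: SnapshotSample) -> np.ndarray:
        vals = snap.marker_values[marker].to_numpy()
        return arcsinh_transform(vals, cofactor) if transform else vals

    ref_vals = marker_values(ref)
    cut = float(np.percentile(ref_vals, q))
    fractions = pd.Series(
        {
            label: float(np.mean(marker_values(snap) > cut))
            for label, snap in zip(labels, snapshots)
        }
    )
    return ThresholdReport(fractions, cut, reference_condition, q)
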