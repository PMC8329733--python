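"""Size-weighted radius histograms and threshold-fraction statistics.

The study-level readout of the pipeline is the distribution of the local
lumen radius, built bottom-up:

1. per object: histogram of the object's per-pixel radius values,
   normalised to unit mass;
2. per image: the object histograms are combined with weights
   ``wᵢ = Aᵢ^(3/2)`` (``Aᵢ`` = pixel count of object *i*, so ``wᵢ`` is
   proportional to the object's estimated volume from its 2D section) and
   renormalised — this discards differences in total apical membrane
   between images;
3. per experiment: unweighted mean over that experiment's images;
4. study level: unweighted mean over experiments, with the per-bin SEM
   (sample SD across experiments / √n) as the dispersion estimate.

The two-level averaging (images within experiment first, then experiments)
makes experiments — not images — the unit of replication: an experiment
with one image carries the same weight as one with four.

Threshold fractions ("percentage of lumina with radius above t µm") come in
two modes: ``mass`` (the default; weighted histogram mass in bins at or
above the threshold) and ``object`` (fraction of objects whose maximum
local radius exceeds the threshold).  Both are reported per experiment and
summarised as mean ± SEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "RadiusHistogram",
    "ThresholdStat",
    "make_bin_edges",
    "object_histogram",
    "object_weight",
    "aggregate_image",
    "average_histograms",
    "fraction_above",
    "EmptyImageError",
]

logger = logging.getLogger(__name__)

_MASS_TOL = 1e-9


class EmptyImageError(ValueError):
    """An image with zero segmented objects cannot contribute a histogram."""


@dataclass
class RadiusHistogram:
    """A unit-mass binned distribution of local lumen radius.

    ``level`` records the aggregation stage (object, image, experiment or
    study); ``sem`` is present only at study level with >= 2 experiments.
    """

    bin_edges: np.ndarray  # µm, uniform width, len = n_bins + 1
    density: np.ndarray  # per-bin mass, sums to 1
    level: str = "object"
    n_contributors: int = 1
    sem: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.density.size + 1:
            raise ValueError("bin_edges must have len(density) + 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if abs(self.density.sum() - 1.0) > _MASS_TOL:
            raise ValueError(
                f"density must sum to 1 (got {self.density.sum():.12f})"
            )

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class ThresholdStat:
    """Percentage of lumina above a radius threshold, per experiment."""

    threshold: float  # µm
    mode: str  # "mass" | "object"
    per_experiment: np.ndarray  # %, one entry per experiment
    mean: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.per_experiment, dtype=float)
        self.per_experiment = v
        self.mean = float(v.mean())
        self.sem = (float(v.std(ddof=1) / np.sqrt(v.size)) if v.size >= 2
                    else float("nan"))


def make_bin_edges(max_radius: float = 10.0, bin_width: float = 0.25) -> np.ndarray:
    """Uniform bin edges over [0, max_radius] µm (default 0.25 µm bins)."""
    n = int(round(max_radius / bin_width))
    if n < 1 or abs(n * bin_width - max_radius) > 1e-9:
        raise ValueError("max_radius must be a multiple of bin_width")
    return np.linspace(0.0, max_radius, n + 1)


def object_histogram(
    radius: np.ndarray,
    labels: np.ndarray,
    object_id: int,
    bin_edges: np.ndarray,
) -> RadiusHistogram:
    """Unit-mass histogram of one object's per-pixel radius values.

    Values at or above the last edge are absorbed into the top bin (they
    arise when the thickness map was computed with a radius cap equal to the
    histogram range).
    """
    labels = np.asarray(labels)
    mask = labels == object_id
    if object_id <= 0 or not mask.any():
        raise KeyError(f"object {object_id} not present in label map")
    vals = np.asarray(radius, dtype=float)[mask]
    edges = np.asarray(bin_edges, dtype=float)
    # np.histogram's last bin is closed; fold the overflow in explicitly
    vals = np.minimum(vals, np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(vals, bins=edges)
    total = counts.sum()
    return RadiusHistogram(
        bin_edges=edges, density=counts / total, level="object", n_contributors=1
    )


def object_weight(A: int) -> float:
    """Volume-proxy weight ``A^(3/2)`` of an object of ``A`` pixels."""
    if A < 1 or int(A) != A:
        raise ValueError(f"pixel count must be a positive integer, got {A}")
    return float(A) ** 1.5


def aggregate_image(
    object_histograms: Sequence[RadiusHistogram],
    weights: Sequence[float],
) -> RadiusHistogram:
    """Weighted sum of object histograms, renormalised to unit mass."""
    if len(object_histograms) == 0:
        raise EmptyImageError("image has no objects; exclude it from averaging")
    if len(object_histograms) != len(weights):
        raise ValueError("one weight per histogram required")
    edges = object_histograms[0].bin_edges
    for h in object_histograms[1:]:
        if not np.array_equal(h.bin_edges, edges):
            raise ValueError("all object histograms must share bin edges")
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    stacked = np.stack([h.density for h in object_histograms])
    density = (w[:, None] * stacked).sum(axis=0) / w.sum()
    density = density / density.sum()  # guard against roundoff drift
    return RadiusHistogram(
        bin_edges=edges, density=density, level="image",
        n_contributors=len(object_histograms),
    )


def average_histograms(
    image_histograms_by_experiment: Sequence[Sequence[RadiusHistogram]],
) -> tuple[RadiusHistogram, List[RadiusHistogram]]:
    """Two-level average: images within experiment, then across experiments.

    Returns the study-level histogram (with per-bin SEM across experiments
    when n >= 2) and the list of experiment-level histograms.  Experiments
    must each contribute at least one image histogram; empty images are the
    caller's responsibility to exclude beforehand.
    """
    if len(image_histograms_by_experiment) == 0:
        raise ValueError("need at least one experiment")
    exp_hists: List[RadiusHistogram] = []
    edges = None
    for i, hists in enumerate(image_histograms_by_experiment):
        if len(hists) == 0:
            raise EmptyImageError(f"experiment {i} contributes no images")
        if edges is None:
            edges = hists[0].bin_edges
        dens = np.stack([h.density for h in hists]).mean(axis=0)
        exp_hists.append(RadiusHistogram(
            bin_edges=edges, density=dens, level="experiment",
            n_contributors=len(hists),
        ))
    n = len(exp_hists)
    stacked = np.stack([h.density for h in exp_hists])
    density = stacked.mean(axis=0)
    if n >= 2:
        sem = stacked.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = None
        logger.warning("single experiment: per-bin SEM omitted")
    study = RadiusHistogram(
        bin_edges=edges, density=density, level="study", n_contributors=n,
        sem=sem,
    )
    return study, exp_hists


def _align_threshold(threshold: float, edges: np.ndarray) -> float:
    i = int(np.argmin(np.abs(edges - threshold)))
    aligned = float(edges[i])
    if abs(aligned - threshold) > 1e-9:
        logger.warning(
            "threshold %.4g µm is not a bin edge; realigned to %.4g µm",
            threshold, aligned,
        )
    return aligned


def fraction_above(
    experiment_histograms: Sequence[RadiusHistogram],
    threshold: float,
    mode: str = "mass",
    object_max_radii_by_experiment: Optional[Sequence[Sequence[float]]] = None,
) -> ThresholdStat:
    """Percentage of lumina with radius above ``threshold`` µm.

    ``mass`` mode: per experiment, 100 × the histogram mass in bins whose
    lower edge is at or above the threshold (bins are half-open ``[lo, hi)``,
    so with an edge-aligned threshold this is exactly the mass above it).
    ``object`` mode: per experiment, 100 × the fraction of objects whose
    maximum local radius exceeds the threshold; requires
    ``object_max_radii_by_experiment``.
    """
    if mode not in ("mass", "object"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mass":
        values = []
        for h in experiment_histograms:
            thr = _align_threshold(threshold, h.bin_edges)
            sel = h.bin_edges[:-1] >= thr - 1e-12
            values.append(100.0 * float(h.density[sel].sum()))
    else:
        if object_max_radii_by_experiment is None:
            raise ValueError("object mode needs per-object maximum radii")
        values = []
        for radii in object_max_radii_by_experiment:
            radii = np.asarray(radii, dtype=float)
            if radii.size == 0:
                raise EmptyImageError("experiment without objects")
            values.append(100.0 * float((radii > threshold).mean()))
    return ThresholdStat(
        threshold=threshold, mode=mode, per_experiment=np.asarray(values)
    )
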