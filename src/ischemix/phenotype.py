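"""Non-dichotomous macrophage polarization analytics.

The M1/M2-like score of a cohort is the log10 of the baseline-normalized
ratio between the product of its eight M1-like markers and the product of its
five M2-like markers; a larger score means an overall more pro-inflammatory
profile.  Population-level views: size-weighted score spectra (histograms)
and cell-averaged marker trajectories, both normalized to the pre-ischemia
control condition.  Scores are computed from accumulated marker levels by
default (configurable to instantaneous production elsewhere); transiently
zero markers are floored at a small fraction of baseline so the log stays
finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signaling import M1_MARKERS, M2_MARKERS, MARKERS

__all__ = [
    "m1m2_score",
    "PhenotypeSpectrum",
    "phenotype_spectrum",
    "population_marker_mean",
    "score_trajectory",
]

_N_M1 = len(M1_MARKERS)


def m1m2_score(panel: np.ndarray, baseline: np.ndarray,
               floor_rel: float = 1e-6) -> float | np.ndarray:
    """Relative M1/M2-like score, log10 transformed.

    ``score = log10[(prod M1 / prod M2) / (prod M1_0 / prod M2_0)]`` with the
    13-marker panel ordered M1 (8) then M2 (5).  ``panel`` may carry leading
    batch axes.  Baseline entries must be strictly positive; panel entries are
    floored at ``floor_rel * baseline`` before taking products.
    """
    panel = np.asarray(panel, float)
    baseline = np.asarray(baseline, float)
    if panel.shape[-1] != len(MARKERS) or baseline.shape != (len(MARKERS),):
        raise ValueError(f"panels must have {len(MARKERS)} markers")
    if np.any(~np.isfinite(baseline)) or np.any(baseline <= 0):
        raise ValueError("baseline marker panel must be strictly positive")
    if np.any(panel < 0):
        raise ValueError("marker panel must be nonnegative")
    rel = np.maximum(panel, floor_rel * baseline) / baseline
    logrel = np.log10(rel)
    score = logrel[..., :_N_M1].sum(axis=-1) - logrel[..., _N_M1:].sum(axis=-1)
    return float(score) if score.ndim == 0 else score


@dataclass
class PhenotypeSpectrum:
    """Size-weighted distribution of cohort scores at one time point."""

    edges: np.ndarray      # len n_bins + 1
    weights: np.ndarray    # len n_bins; sums to the total macrophage count
    scores: np.ndarray     # per-cohort scores
    sizes: np.ndarray      # per-cohort sizes

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def mean_score(self) -> float:
        if self.sizes.sum() == 0:
            raise ZeroDivisionError("empty spectrum has no mean score")
        return float(np.average(self.scores, weights=self.sizes))

    def to_frame(self, time_day: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center": self.centers, "weight": self.weights})
        if time_day is not None:
            df.insert(0, "time_day", time_day)
        return df


def phenotype_spectrum(
    panels: np.ndarray,
    sizes: np.ndarray,
    baseline: np.ndarray,
    bins: int = 40,
    score_range: tuple[float, float] | None = None,
    floor_rel: float = 1e-6,
) -> PhenotypeSpectrum:
    """Histogram of cohort M1/M2-like scores weighted by cohort size.

    Total histogram weight equals the total macrophage count.  An empty
    cohort list yields an empty spectrum.
    """
    sizes = np.asarray(sizes, float)
    if sizes.size == 0:
        return PhenotypeSpectrum(edges=np.array([0.0, 1.0]),
                                 weights=np.zeros(1), scores=np.zeros(0),
                                 sizes=np.zeros(0))
    if np.any(sizes < 0):
        raise ValueError("cohort sizes must be >= 0")
    scores = np.atleast_1d(m1m2_score(panels, baseline, floor_rel))
    if score_range is None:
        lo, hi = scores.min(), scores.max()
        pad = max(1e-6, 0.05 * (hi - lo))
        score_range = (lo - pad, hi + pad)
    weights, edges = np.histogram(scores, bins=bins, range=score_range,
                                  weights=sizes)
    return PhenotypeSpectrum(edges=edges, weights=weights, scores=scores,
                             sizes=sizes)


def population_marker_mean(
    panels: np.ndarray,
    sizes: np.ndarray,
    baseline: np.ndarray,
    marker: str | None = None,
) -> float | pd.Series:
    """Cell-averaged marker expression, normalized to the pre-HLI control.

    Size-weighted mean across cohorts, divided by the control-condition
    panel.  Returns one value for ``marker`` or a Series over all 13.
    """
    sizes = np.asarray(sizes, float)
    total = sizes.sum()
    if total <= 0:
        raise ZeroDivisionError("population marker mean undefined: no cells")
    panels = np.asarray(panels, float)
    mean = sizes @ panels / total
    norm = pd.Series(mean / np.asarray(baseline, float), index=MARKERS)
    if marker is not None:
        return float(norm[marker])
    return norm


def score_trajectory(result, floor_rel: float = 1e-6) -> pd.DataFrame:
    """Size-weighted mean score and census at every interval end of a run."""
    rows = []
    for t_h, sizes, panels in zip(result.interval_end_hours,
                                  result.cohort_sizes, result.cohort_panels):
        if len(sizes) == 0 or sizes.sum() == 0:
            continue
        scores = m1m2_score(panels, result.marker0, floor_rel)
        rows.append({
            "time_day": t_h / 24.0,
            "mean_score": float(np.average(scores, weights=sizes)),
            "total_macrophages": float(sizes.sum()),
        })
    return pd.DataFrame(rows)
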