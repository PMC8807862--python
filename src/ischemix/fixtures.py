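"""Synthetic fixture generation.

The published calibration targets are literature-digitized curves that are
not redistributable; these generators produce structurally equivalent
synthetic targets from the model itself: (a) max-normalized HMGB1-response
time courses of the signaling readouts and phenotype markers, with optional
multiplicative noise, for calibration exercises; and (b) a perfusion
acceptance envelope (mean +- k SD across a small perturbed cohort) standing
in for the curated in vivo recovery data used to admit virtual mice.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import load_config
from .inference import CalibrationDataset, PerfusionEnvelope, _resample, _simulate_curves
from .multiscale import Protocol, simulate

__all__ = ["FixtureSpec", "make_fixture_dataset", "make_perfusion_envelope"]

#: default roster of max-normalized response curves (signaling + markers)
DEFAULT_CURVES = ["PI3K", "ERK", "P38", "JNK", "IkB_degradation",
                  "mTNFa", "mIL12", "mIL10"]


@dataclass
class FixtureSpec:
    """What to generate: curve roster, stimulus, noise level and seed."""

    curves: tuple[str, ...] = tuple(DEFAULT_CURVES)
    t_hours: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.25, 24.0, 25))
    stimulus_hmgb1: float = 1.0
    hypoxia: float = 0.0
    noise: float = 0.0
    seed: int = 0
    generating_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not self.curves:
            raise ValueError("curve roster must be non-empty")


def make_fixture_dataset(spec: FixtureSpec) -> CalibrationDataset:
    """Simulate the declared curves and add multiplicative noise."""
    base = CalibrationDataset(
        curves={c: (np.asarray(spec.t_hours, float),
                    np.zeros(len(spec.t_hours))) for c in spec.curves},
        stimulus_hmgb1=spec.stimulus_hmgb1,
        hypoxia=spec.hypoxia,
    )
    sim = _simulate_curves(spec.generating_params, base)
    rng = np.random.default_rng(spec.seed)
    curves = {}
    for c in spec.curves:
        v = sim[c]
        if spec.noise > 0:
            v = v * (1.0 + spec.noise * rng.standard_normal(len(v)))
        curves[c] = (np.asarray(spec.t_hours, float), v)
    return CalibrationDataset(curves=curves, stimulus_hmgb1=spec.stimulus_hmgb1,
                              hypoxia=spec.hypoxia)


def make_perfusion_envelope(
    n_mice: int = 20,
    seed: int = 11,
    k_sd: float | None = None,
    run_config: dict | None = None,
) -> PerfusionEnvelope:
    """Envelope from a perturbed cohort: mean +- k SD at each checkpoint.

    Simulates ``n_mice`` parameter draws (the same log-uniform resampling
    spec used for VMP generation) under acute and gradual protocols and
    summarizes the perfusion trajectories at the configured checkpoints.
    """
    rc = run_config or load_config()
    vmp_cfg = rc["vmp"]
    k = float(vmp_cfg["envelope_k_sd"]) if k_sd is None else k_sd
    checkpoints = np.asarray(vmp_cfg["checkpoints_days"], float)
    from .tissue import build_baseline

    base = build_baseline(config=rc)
    bounds = {p.name: (p.lower, p.upper) for p in base.tissue.doc.parameters}
    rng = np.random.default_rng(seed)
    lower, upper = {}, {}
    draws = [_resample(base.tissue.params, vmp_cfg["resample"], rng, bounds)
             for _ in range(n_mice)]
    for mode in ("acute", "gradual"):
        vals = np.empty((n_mice, len(checkpoints)))
        for i, params in enumerate(draws):
            res = simulate(Protocol(mode), params=params, run_config=rc)
            vals[i] = np.interp(checkpoints, res.t_days, res.normalized("Perfusion"))
        mu, sd = vals.mean(0), vals.std(0, ddof=1)
        lower[mode] = np.maximum(0.0, mu - k * sd)
        upper[mode] = mu + k * sd
    return PerfusionEnvelope(checkpoints_days=checkpoints, lower=lower, upper=upper)


def write_fixture_files(outdir: str | Path, dataset: CalibrationDataset,
                        envelope: PerfusionEnvelope) -> dict[str, Path]:
    """Write the calibration CSV and envelope CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calibration": outdir / "calibration_curves.csv",
        "envelope": outdir / "perfusion_envelope.csv",
    }
    dataset.to_frame().to_csv(paths["calibration"], index=False)
    envelope.to_frame().to_csv(paths["envelope"], index=False)
    return paths
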