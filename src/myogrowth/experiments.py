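"""Reproducible experiment drivers for the published perturbation studies.

Four scans probe the coupled model around the baseline 8-week protocol:

* :func:`sensitivity_scan` -- one-at-a-time +/-1% perturbations of the
  twelve pathway rate/coupling constants; per run it reports the change of
  the maximum normalized CSA (percentage points, both as pp of baseline
  area and as relative %) and the RMSE of the CSA curve against the
  *baseline simulation* (the external experimental series is not printed,
  so the baseline curve is the declared reference).
* :func:`frequency_scan` -- training daily, every 2 days, three times per
  week, every 3 days.
* :func:`kappa_scan` -- myofibril areal density kappa relative to
  kappa0 = z(0)/A(0): smaller kappa (larger initial myofibrils) grows more.
* :func:`linear_k1_scan` -- straight-line surrogate k1/k10 = b - m A for
  the activation feedback, plus a least-squares fit of the slope realized
  by the beta-feedback reference run.

Every report is regenerable bit-identically from its configuration hash:
the pipeline contains no randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .params import SimulationConfig, config_hash
from .simulation import SimulationResult, run_protocol

__all__ = [
    "PATHWAY_SCAN_PARAMETERS",
    "FREQUENCY_PROTOCOLS",
    "ScanSpec",
    "ScanReport",
    "sensitivity_scan",
    "frequency_scan",
    "kappa_scan",
    "linear_k1_scan",
    "fit_feedback_slope",
]

logger = logging.getLogger(__name__)

#: the twelve rate/coupling constants probed by the one-at-a-time scan.
PATHWAY_SCAN_PARAMETERS = (
    "a10", "a20", "a3", "a4",
    "b1", "b2", "b3", "b4",
    "c21", "c32", "c42", "c43",
)

#: named training frequencies of the frequency scan.
FREQUENCY_PROTOCOLS = ("daily", "every-2-days", "three-per-week", "every-3-days")


@dataclass
class ScanSpec:
    """One-at-a-time perturbation specification."""

    parameters: Sequence[str] = PATHWAY_SCAN_PARAMETERS
    perturbations: Sequence[float] = (-0.01, +0.01)

    def __post_init__(self) -> None:
        if any(p == 0 for p in self.perturbations):
            raise ValueError("perturbations must be non-zero")
        from .params import PathwayParameters

        valid = {f.name for f in dataclasses.fields(PathwayParameters)}
        unknown = set(self.parameters) - valid
        if unknown:
            raise ValueError(f"unknown pathway parameters: {sorted(unknown)}")


@dataclass
class ScanReport:
    """Tabular scan result plus baseline summary and provenance."""

    table: pd.DataFrame
    baseline: dict
    config_hash: str
    package_version: str = _pkg_version

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baseline": self.baseline,
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _baseline_summary(res: SimulationResult) -> dict:
    return {
        "max_area_norm": res.max_area_norm,
        "final_area_norm": res.final_area_norm,
        "max_csa_increase_pp": (res.max_area_norm - 1.0) * 100.0,
        "f_max_kgf": res.f_max_kgf,
        "load_kgf": res.load_kgf,
    }


def _csa_metrics(res: SimulationResult, base: SimulationResult) -> dict:
    """Max-CSA change (pp and relative %) and RMSE vs the baseline curve."""
    d_max = res.max_area_norm - base.max_area_norm
    rmse = float(np.sqrt(np.mean((res.area_norm - base.area_norm) ** 2)))
    return {
        "max_area_norm": res.max_area_norm,
        "max_csa_change_pp": d_max * 100.0,
        "max_csa_change_rel_pct": d_max / base.max_area_norm * 100.0,
        "rmse_vs_baseline": rmse,
    }


def sensitivity_scan(
    config: Optional[SimulationConfig] = None,
    spec: Optional[ScanSpec] = None,
) -> ScanReport:
    """+/-1% one-at-a-time scan of the pathway parameters.

    A failed run is recorded with ``status`` and NaN metrics; the scan
    continues.  A zero perturbation would reproduce the baseline exactly
    (identical code path, no randomness).
    """
    cfg = config if config is not None else SimulationConfig()
    spec = spec if spec is not None else ScanSpec()
    base = run_protocol(cfg)
    rows = [{
        "parameter": "baseline", "perturbation": 0.0, "value": np.nan,
        "status": "ok", **_csa_metrics(base, base),
    }]
    for name in spec.parameters:
        for rel in spec.perturbations:
            value = getattr(cfg.pathway, name) * (1.0 + rel)
            pathway = replace(cfg.pathway, **{name: value})
            try:
                res = run_protocol(cfg, pathway_params=pathway)
                metrics = _csa_metrics(res, base)
                status = "ok"
            except Exception as exc:  # record the failure, keep scanning
                logger.warning("run %s%+.2f%% failed: %s", name, rel * 100, exc)
                metrics = dict.fromkeys(
                    ("max_area_norm", "max_csa_change_pp",
                     "max_csa_change_rel_pct", "rmse_vs_baseline"), np.nan)
                status = f"failed: {exc}"
            rows.append({"parameter": name, "perturbation": rel,
                         "value": value, "status": status, **metrics})
    return ScanReport(
        table=pd.DataFrame(rows),
        baseline=_baseline_summary(base),
        config_hash=config_hash(cfg),
    )


def _protocol_for_frequency(cfg: SimulationConfig, name: str):
    base = cfg.protocol
    if name == "three-per-week":
        return base
    days = {"daily": 1, "every-2-days": 2, "every-3-days": 3}[name]
    return replace(base, every_n_days=days, session_days=(1, 3, 5),
                   n_sessions=None)


def frequency_scan(
    config: Optional[SimulationConfig] = None,
    frequencies: Sequence[str] = FREQUENCY_PROTOCOLS,
) -> ScanReport:
    """Maximal CSA increase under different training frequencies."""
    cfg = config if config is not None else SimulationConfig()
    base = run_protocol(cfg)
    rows = []
    for name in frequencies:
        protocol = _protocol_for_frequency(cfg, name)
        res = (base if protocol is cfg.protocol
               else run_protocol(cfg, protocol=protocol))
        rows.append({
            "frequency": name,
            "n_sessions": len(res.feedback),
            **_csa_metrics(res, base),
        })
    return ScanReport(table=pd.DataFrame(rows),
                      baseline=_baseline_summary(base),
                      config_hash=config_hash(cfg))


def kappa_scan(
    config: Optional[SimulationConfig] = None,
    ratios: Sequence[float] = (0.7, 0.85, 1.0, 1.15),
) -> ScanReport:
    """Maximal CSA increase as a function of kappa/kappa0.

    kappa scales the myofibril count per unit area; a subject with kappa =
    0.7 kappa0 carries 70% of the reference myofibril population per cm^2,
    so each unit of myofibril production buys more area.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("kappa ratios must be positive")
    cfg = config if config is not None else SimulationConfig()
    base = run_protocol(cfg)
    rows = []
    for ratio in ratios:
        if ratio == cfg.protocol.kappa_ratio:
            res = base
        else:
            res = run_protocol(cfg, protocol=replace(cfg.protocol,
                                                     kappa_ratio=ratio))
        rows.append({"kappa_ratio": ratio, **_csa_metrics(res, base)})
    return ScanReport(table=pd.DataFrame(rows),
                      baseline=_baseline_summary(base),
                      config_hash=config_hash(cfg))


def fit_feedback_slope(res: SimulationResult) -> tuple[float, float]:
    """Least-squares straight line k1/k10 = b - m A to the feedback samples.

    One (A, k1/k10) point per k1-update event, A in m^2, unweighted.
    Returns (m, b) with m > 0 for a decreasing relation.  Raises if the
    sampled k1 is constant (degenerate fit).
    """
    ev = res.feedback
    if len(ev) < 2:
        raise ValueError("need at least two feedback samples to fit a slope")
    y = ev["k1_ratio"].to_numpy()
    if float(np.ptp(y)) == 0.0:
        raise ValueError("degenerate fit: k1 constant over the run")
    coef = np.polyfit(ev["area_m2"].to_numpy(), y, 1)
    return (-float(coef[0]), float(coef[1]))


def linear_k1_scan(
    config: Optional[SimulationConfig] = None,
    slopes: Sequence[float] = (1720.0, 3440.0, 6880.0),
) -> ScanReport:
    """Linear-feedback surrogate runs plus the beta-feedback reference.

    Each linear run uses k1/k10 = b - m A with the intercept fixed so the
    ratio at the initial CSA matches the beta-feedback value there.  The
    report also carries the least-squares slope fitted to the reference
    run's own (A, k1/k10) samples.
    """
    cfg = config if config is not None else SimulationConfig()
    fb_beta = replace(cfg.feedback, mode="beta")
    base = run_protocol(cfg, fb=fb_beta)
    m_fit, b_fit = fit_feedback_slope(base)
    rows = [{"mode": "beta-reference", "slope_m": np.nan,
             **_csa_metrics(base, base)}]
    for m in slopes:
        fb = replace(cfg.feedback, mode="linear", slope_m=m, intercept_b=None)
        res = run_protocol(cfg, fb=fb)
        rows.append({"mode": "linear", "slope_m": m, **_csa_metrics(res, base)})
    report = ScanReport(table=pd.DataFrame(rows),
                        baseline=_baseline_summary(base),
                        config_hash=config_hash(cfg))
    report.baseline["fitted_slope_per_m2"] = m_fit
    report.baseline["fitted_intercept"] = b_fit
    return report
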