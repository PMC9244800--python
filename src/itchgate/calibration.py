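"""Calibration targets and synthetic test data.

This package ships no recordings: every calibration number is a published
group-level value (means, group sizes, relative changes) stored in
``data/printed_values.yaml`` and exposed through :class:`PrintedValueTable`.
Quantities that were published only as relative changes or figure panels
(absolute control rheobase, spike counts at 60 pA, absolute maximum dV/dt)
enter the target sets through explicit, overridable anchor values
(:class:`CalibrationAnchors`) that are documented assumptions, not
measurements.

The module also generates surrogate per-cell feature samples (Gaussian per
metric around the group values) and synthetic voltage traces with planted,
analytically known features, which the feature-extraction tests use as
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType

import numpy as np
import yaml

from .cable import VoltageTrace
from .population import MetricTarget, TargetSet

__all__ = [
    "PrintedValueTable",
    "printed_values",
    "CalibrationAnchors",
    "target_set",
    "SurrogateSample",
    "make_surrogate_population",
    "make_test_trace",
    "MISSING",
]

CELL_CLASSES = ("ucn3", "npy")
GROUPS = ("control", "calcipotriol")

#: marker for published-as-relative-change-only quantities
MISSING = None

#: default dispersion (coefficient of variation) where no spread was published
DEFAULT_CV = 0.20


def _deep_freeze(obj):
    if isinstance(obj, dict):
        return MappingProxyType({k: _deep_freeze(v) for k, v in obj.items()})
    if isinstance(obj, list):
        return tuple(_deep_freeze(v) for v in obj)
    return obj


class PrintedValueTable:
    """Immutable table of the published group-level values.

    Access with ``table.entry(cell_class, metric)`` (the raw tagged record)
    or ``table.value(cell_class, group, metric)``, which returns the absolute
    group value or :data:`MISSING` when only a relative change was published
    (the relative change is then available as the ``<metric>_change_pct``
    entry).
    """

    def __init__(self) -> None:
        raw = yaml.safe_load(
            resources.files("itchgate").joinpath("data/printed_values.yaml").read_text()
        )
        self.version = raw.pop("version")
        self._data = _deep_freeze(raw)

    def cell_classes(self):
        return tuple(self._data)

    def metrics(self, cell_class: str):
        return tuple(self._data[cell_class])

    def entry(self, cell_class: str, metric: str):
        try:
            return self._data[cell_class][metric]
        except KeyError:
            raise KeyError(f"no published entry for {cell_class}/{metric}") from None

    def value(self, cell_class: str, group: str, metric: str):
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        e = self.entry(cell_class, metric)
        if group in e:
            return e[group]["value"]
        if "value" in e and not isinstance(e["value"], str):
            return MISSING  # published as relative change only
        return e.get("value", MISSING)

    def change_pct(self, cell_class: str, metric: str):
        return self.entry(cell_class, f"{metric}_change_pct")["value"]

    def firing_pattern(self, cell_class: str) -> str:
        return self.entry(cell_class, "firing_pattern")["value"]


_TABLE = None


def printed_values() -> PrintedValueTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = PrintedValueTable()
    return _TABLE


@dataclass(frozen=True)
class CalibrationAnchors:
    """Assumed absolute control-group values for metrics published only as
    relative changes or figure panels.  All overridable; dispersions for the
    derived targets use :data:`DEFAULT_CV`."""

    rheobase_pA: float = 40.0
    n_spikes_60pA_ucn3: float = 3.0
    n_spikes_60pA_npy: float = 8.0

    def n_spikes(self, cell_class: str) -> float:
        return self.n_spikes_60pA_ucn3 if cell_class == "ucn3" else self.n_spikes_60pA_npy


def target_set(
    cell_class: str,
    group: str = "control",
    anchors: CalibrationAnchors | None = None,
    cv: float = DEFAULT_CV,
) -> TargetSet:
    """Build the MCMC scoring targets for one cell class and treatment group.

    Published absolute values (AP threshold, half-width) are used directly;
    rheobase and the 60 pA spike count are anchored (see
    :class:`CalibrationAnchors`), with the published relative rheobase
    change applied for the calcipotriol group.  Maximum dV/dt is extracted
    and reported for every model but is not scored: only its relative change
    was published, and scoring it would pin the fit to an arbitrary absolute
    anchor.  Dispersion scales default to ``cv`` times the target magnitude
    (no per-metric spreads were published).
    """
    if cell_class not in CELL_CLASSES:
        raise KeyError(f"unknown cell class {cell_class!r}")
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    anchors = anchors or CalibrationAnchors()
    tab = printed_values()

    rheo = anchors.rheobase_pA
    if group == "calcipotriol":
        rheo *= 1.0 + tab.change_pct(cell_class, "rheobase") / 100.0

    def mt(value, floor=0.0):
        # dispersion below a metric's own granularity (one spike for counts)
        # would over-constrain the score
        return MetricTarget(value=value, dispersion=max(abs(value) * cv, floor))

    metrics = {
        "rheobase_pA": mt(rheo),
        "n_spikes_60pA": mt(anchors.n_spikes(cell_class), floor=1.0),
        "ap_threshold_mV": mt(tab.value(cell_class, group, "ap_threshold_mV")),
        "half_width_ms": mt(tab.value(cell_class, group, "half_width_ms")),
    }
    return TargetSet(
        cell_class=cell_class,
        group=group,
        metrics=metrics,
        required_pattern=tab.firing_pattern(cell_class),
    )


# ---------------------------------------------------------------------------
# Surrogate experimental samples


@dataclass
class SurrogateSample:
    """Reproducible Gaussian surrogate draws standing in for per-cell
    experimental feature measurements (only group statistics were
    published).  Synthetic data, not recordings."""

    cell_class: str
    group: str
    seed: int
    draws: dict  # {metric: np.ndarray}
    means: dict
    sds: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws)


def make_surrogate_population(
    cell_class: str,
    group: str = "control",
    n: int = 100,
    seed: int = 0,
    anchors: CalibrationAnchors | None = None,
    cv: float = DEFAULT_CV,
) -> SurrogateSample:
    """Draw ``n`` surrogate cells: per metric, Gaussian around the group
    value with SD = cv * |mean| (no per-metric SDs were published)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    targets = target_set(cell_class, group, anchors=anchors, cv=cv)
    rng = np.random.default_rng(seed)
    draws, means, sds = {}, {}, {}
    for name, mtarget in targets.metrics.items():
        mu, sd = mtarget.value, mtarget.dispersion
        draws[name] = rng.normal(mu, sd, size=n)
        means[name], sds[name] = mu, sd
    return SurrogateSample(
        cell_class=cell_class, group=group, seed=seed, draws=draws, means=means, sds=sds
    )


# ---------------------------------------------------------------------------
# Synthetic voltage traces with planted features


TRACE_KINDS = ("flat", "rc_charging", "planted_spikes", "ramp_spike", "gaussian_ap", "triangular")


def make_test_trace(kind: str, params: dict | None = None, seed: int = 0) -> VoltageTrace:
    """Synthetic somatic traces whose features are known analytically.

    kinds:
      flat            constant baseline (no spikes)
      rc_charging     V0 + I*R*(1 - exp(-t/tau)) from ``delay``
      planted_spikes  ``k`` triangular spikes at known times
      ramp_spike      slow ramp to a planted threshold voltage ``v_star``,
                      then a fast rise to the peak (10 mV/ms crossing at v_star)
      gaussian_ap     Gaussian spike of width sigma (FWHM = 2*sigma*sqrt(2 ln 2))
      triangular      symmetric triangle, base width w (half-width = w/2)
    """
    p = dict(params or {})
    dt = p.get("dt_ms", 0.02)
    dur = p.get("duration_ms", 200.0)
    base = p.get("baseline_mV", -65.0)
    n = int(round(dur / dt)) + 1
    t = np.arange(n) * dt
    v = np.full(n, base)
    stim = np.zeros(n)

    if kind == "flat":
        pass
    elif kind == "rc_charging":
        R = p.get("R_Mohm", 500.0)
        tau = p.get("tau_ms", 20.0)
        amp = p.get("amplitude_pA", 20.0)
        delay = p.get("delay_ms", 10.0)
        on = t >= delay
        v[on] = base + amp * 1e-3 * R * (1.0 - np.exp(-(t[on] - delay) / tau))
        stim[on] = amp
    elif kind == "planted_spikes":
        k = int(p.get("k", 5))
        peak = p.get("peak_mV", 30.0)
        width = p.get("width_ms", 2.0)
        first, gap = p.get("first_ms", 20.0), p.get("gap_ms", 20.0)
        for i in range(k):
            t0 = first + i * gap
            tri = 1.0 - np.abs(t - t0) / (width / 2.0)
            np.maximum(v, base + (peak - base) * np.clip(tri, 0.0, 1.0), out=v)
    elif kind == "ramp_spike":
        v_star = p.get("v_star_mV", -40.0)
        ramp_slope = p.get("ramp_slope_mV_ms", 2.0)
        rise_slope = p.get("rise_slope_mV_ms", 100.0)
        peak = p.get("peak_mV", 30.0)
        t_thr = (v_star - base) / ramp_slope
        t_pk = t_thr + (peak - v_star) / rise_slope
        v = np.where(t < t_thr, base + ramp_slope * t, v)
        rise = (t >= t_thr) & (t < t_pk)
        v[rise] = v_star + rise_slope * (t[rise] - t_thr)
        after = t >= t_pk
        v[after] = peak - 20.0 * (t[after] - t_pk)
        np.maximum(v, base, out=v)
    elif kind == "gaussian_ap":
        sigma = p.get("sigma_ms", 0.25)
        peak = p.get("peak_mV", 30.0)
        t0 = p.get("t0_ms", dur / 2.0)
        v = base + (peak - base) * np.exp(-((t - t0) ** 2) / (2.0 * sigma**2))
    elif kind == "triangular":
        w = p.get("base_width_ms", 4.0)
        peak = p.get("peak_mV", 30.0)
        t0 = p.get("t0_ms", dur / 2.0)
        tri = 1.0 - np.abs(t - t0) / (w / 2.0)
        v = base + (peak - base) * np.clip(tri, 0.0, 1.0)
    else:
        raise KeyError(f"unknown test-trace kind {kind!r}; expected one of {TRACE_KINDS}")

    noise_sd = p.get("noise_sd_mV", 0.0)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return VoltageTrace(time_ms=t, voltage_mV={"soma": v}, stimulus_pA=stim, dt_ms=dt)
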