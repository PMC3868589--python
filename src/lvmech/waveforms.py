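"""Synthetic cardiac-cycle pressure/volume waveforms and the active-elastance rule.

The tool needs a sampled left-ventricular (LV) cavity pressure p(t) and a
target cavity volume V(t) over one cardiac cycle. For the reference healthy
cycle only anchor values are available in print (EDV = 130 ml, ESV = 50 ml,
stroke volume 80 ml, peak pressure 16.93 kPa, phase-boundary times
0.1/0.21/0.3/0.43/0.5/0.65 s of a 0.8 s cycle), so the generator
reconstructs smooth curves through those anchors with monotone piecewise
cubic (PCHIP) interpolation. Both isovolumic phases are exactly constant in
volume by construction.

The active myofiber Young's modulus is tied to the cavity pressure by the
active-elastance hypothesis: E_a(t) = c_act * p(t), with c_act chosen so the
modulus peaks at e_max = 0.5 MPa at peak pressure (c_act = 500/16.93 = 29.5
for the reference cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PHASES",
    "ActiveElastanceRule",
    "CycleSpec",
    "CycleData",
    "build_reference_cycle_spec",
    "generate_cycle",
    "active_modulus",
    "load_cycle_csv",
]

#: Cardiac-cycle phases in order; each ends at the matching entry of
#: ``CycleSpec.phase_times``.
PHASES = (
    "atrial_systole",
    "isovolumic_contraction",
    "rapid_ejection",
    "reduced_ejection",
    "isovolumic_relaxation",
    "rapid_filling",
    "reduced_filling",
)


class WaveformError(ValueError):
    """Inconsistent cycle anchors or malformed cycle input."""


@dataclass(frozen=True)
class ActiveElastanceRule:
    """E_a = c_act * p with a cap e_max on the attainable modulus.

    Parameters
    ----------
    e_max : float
        Maximum active myofiber Young's modulus, kPa (default 500 = 0.5 MPa).
    c_act : float
        Dimensionless proportionality between cavity pressure and active
        modulus, ``e_max / p_peak``.
    """

    e_max: float = 500.0
    c_act: float = 500.0 / 16.93

    @classmethod
    def for_peak_pressure(cls, p_peak: float, e_max: float = 500.0) -> "ActiveElastanceRule":
        if p_peak <= 0:
            raise WaveformError(f"p_peak must be positive, got {p_peak}")
        return cls(e_max=e_max, c_act=e_max / p_peak)


def active_modulus(p, rule: ActiveElastanceRule):
    """Active myofiber Young's modulus E_a = c_act * p [kPa]."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise WaveformError("negative pressure passed to active_modulus")
    return rule.c_act * p


@dataclass(frozen=True)
class CycleSpec:
    """Anchor description of one cardiac cycle.

    Times in s, volumes in ml, pressures in kPa. ``phase_times`` are the ends
    of the seven phases in :data:`PHASES`; the last equals ``cycle_length``.
    ``p_anchors`` are pressures at t=0 followed by the seven phase boundaries.
    ``v_end_rapid_ejection`` / ``v_end_rapid_filling`` are the two interior
    volume anchors that no printed value fixes; left as None they default to
    75% of the stroke volume being ejected during rapid ejection and ~92% of
    the refill to v_start being completed during rapid filling (70 and 105 ml
    for the reference cycle).
    """

    cycle_length: float = 0.8
    phase_times: tuple = (0.1, 0.21, 0.3, 0.43, 0.5, 0.65, 0.8)
    v_start: float = 110.0
    edv: float = 130.0
    esv: float = 50.0
    p_peak: float = 16.93
    p_anchors: tuple = (0.5, 1.0, 10.6, 16.93, 13.0, 0.7, 0.35, 0.5)
    v_end_rapid_ejection: float | None = None
    v_end_rapid_filling: float | None = None
    n_samples: int = 41

    # interior anchor fractions (dimensionless); only used when the
    # corresponding absolute anchor is None
    rapid_ejection_fraction: float = 0.75
    rapid_filling_fraction: float = 11.0 / 12.0

    def _v_rapid_ejection_end(self) -> float:
        if self.v_end_rapid_ejection is not None:
            return self.v_end_rapid_ejection
        return self.edv - self.rapid_ejection_fraction * (self.edv - self.esv)

    def _v_rapid_filling_end(self) -> float:
        if self.v_end_rapid_filling is not None:
            return self.v_end_rapid_filling
        return self.esv + self.rapid_filling_fraction * (self.v_start - self.esv)

    def validate(self) -> None:
        pt = np.asarray(self.phase_times)
        if len(pt) != len(PHASES):
            raise WaveformError(f"need {len(PHASES)} phase times, got {len(pt)}")
        if np.any(np.diff(np.concatenate([[0.0], pt])) <= 0):
            raise WaveformError(f"phase_times must be strictly increasing: {pt}")
        if not np.isclose(pt[-1], self.cycle_length):
            raise WaveformError("last phase time must equal cycle_length")
        if not (self.edv > self.esv > 0):
            raise WaveformError(f"need edv > esv > 0, got edv={self.edv}, esv={self.esv}")
        if self.v_start > self.edv:
            raise WaveformError("v_start must not exceed edv")
        if self.p_peak <= 0:
            raise WaveformError("p_peak must be positive")
        if len(self.p_anchors) != len(PHASES) + 1:
            raise WaveformError("p_anchors must hold t=0 plus one value per phase boundary")
        if np.any(np.asarray(self.p_anchors) < 0):
            raise WaveformError("pressure anchors must be non-negative")
        if max(self.p_anchors) > self.p_peak + 1e-12:
            raise WaveformError("pressure anchors may not exceed p_peak")
        if self.n_samples < len(pt) + 1:
            raise WaveformError("n_samples must cover the phase breakpoints")
        v_re, v_rf = self._v_rapid_ejection_end(), self._v_rapid_filling_end()
        if not (self.esv < v_re < self.edv):
            raise WaveformError(
                f"rapid-ejection end volume {v_re} must lie between ESV and EDV"
            )
        if not (self.esv < v_rf <= self.v_start):
            raise WaveformError(
                f"rapid-filling end volume {v_rf} must lie between ESV and v_start"
            )

    # anchor tables -------------------------------------------------------
    def anchor_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.phase_times, dtype=float)])

    def volume_anchors(self) -> np.ndarray:
        # volumes at t=0 and each phase end; both isovolumic phases flat,
        # cycle closes back at v_start.
        return np.array(
            [
                self.v_start,
                self.edv,  # end atrial systole (end diastole)
                self.edv,  # end isovolumic contraction
                self._v_rapid_ejection_end(),
                self.esv,  # end reduced ejection (end systole)
                self.esv,  # end isovolumic relaxation
                self._v_rapid_filling_end(),
                self.v_start,
            ]
        )


@dataclass(frozen=True)
class CycleData:
    """Sampled cycle: time grid with pressure, target volume and E_a series."""

    t: np.ndarray
    p: np.ndarray
    v_target: np.ndarray
    e_active: np.ndarray
    spec: CycleSpec | None = None
    rule: ActiveElastanceRule = field(default_factory=ActiveElastanceRule)

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.p) == len(self.v_target) == len(self.e_active) == n):
            raise WaveformError("all cycle series must share the time grid length")
        if np.any(np.diff(self.t) <= 0):
            raise WaveformError("time grid must be strictly increasing")
        if np.any(self.p < 0):
            raise WaveformError("pressures must be non-negative")
        if np.any(self.v_target <= 0):
            raise WaveformError("target volumes must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "p_kPa": self.p,
                "v_ml": self.v_target,
                "e_active_kPa": self.e_active,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_reference_cycle_spec(n_samples: int = 41) -> CycleSpec:
    """The reference healthy cycle (EDV 130, ESV 50 ml, peak 16.93 kPa)."""
    return CycleSpec(n_samples=n_samples)


def generate_cycle(spec: CycleSpec, rule: ActiveElastanceRule | None = None) -> CycleData:
    """Sample p(t), V(t) and E_a(t) from an anchor spec.

    PCHIP through the anchors keeps each phase monotone, reproduces every
    anchor exactly and renders the isovolumic plateaus exactly constant.
    """
    spec.validate()
    if rule is None:
        rule = ActiveElastanceRule.for_peak_pressure(spec.p_peak)
    t_anchor = spec.anchor_times()
    t = np.linspace(0.0, spec.cycle_length, spec.n_samples)
    v = PchipInterpolator(t_anchor, spec.volume_anchors())(t)
    p = PchipInterpolator(t_anchor, np.asarray(spec.p_anchors, dtype=float))(t)
    p = np.clip(p, 0.0, None)
    e = active_modulus(p, rule)
    return CycleData(t=t, p=p, v_target=v, e_active=e, spec=spec, rule=rule)


def load_cycle_csv(path, rule: ActiveElastanceRule | None = None,
                   p_peak: float | None = None) -> CycleData:
    """Load a user-supplied (t, p, v) CSV and attach the E_a schedule.

    Columns ``t_s``/``t``, ``p_kPa``/``p``, ``v_ml``/``v`` are accepted.
    Unless ``p_peak`` is given, the elastance constant uses the loaded
    pressure maximum.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return df[cols[n]].to_numpy(dtype=float)
        raise WaveformError(f"CSV is missing a column named one of {names}")

    t = pick("t_s", "t")
    p = pick("p_kpa", "p")
    v = pick("v_ml", "v")
    if rule is None:
        peak = p_peak if p_peak is not None else float(np.max(p))
        rule = ActiveElastanceRule.for_peak_pressure(peak)
    return CycleData(t=t, p=p, v_target=v, e_active=active_modulus(p, rule), rule=rule)
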