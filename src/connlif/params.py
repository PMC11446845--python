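"""Biophysical parameters of the leaky integrate-and-fire point-neuron model.

The model has a single free parameter, ``w_syn`` — the membrane-drive
increment (mV) contributed by one synapse. Every other constant comes from
published *Drosophila* electrophysiology / modelling values. The membrane
time constant is always derived from R and C and never stored separately.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass(frozen=True)
class LIFParameters:
    """Constants of the three-equation LIF model.

    Units: potentials in mV, times in ms, ``r_mbr`` in kOhm*cm^2 and
    ``c_mbr`` in uF/cm^2 (so their product is a time in ms).

    Attributes
    ----------
    v_resting : resting membrane potential (mV).
    v_reset : potential the membrane is reset to after a spike (mV).
    v_threshold : spiking threshold (mV); spike on ``v >= v_threshold``.
    r_mbr, c_mbr : specific membrane resistance and capacitance.
    tau : synaptic-drive decay time constant (ms); ``math.inf`` disables
        synaptic decay (useful for analytic charging checks).
    t_refractory : absolute refractory period (ms).
    t_dly : spike-to-effect transmission delay (ms).
    w_syn : per-synapse weight (mV) — the model's one free parameter.
    """

    v_resting: float = -52.0
    v_reset: float = -52.0
    v_threshold: float = -45.0
    r_mbr: float = 10.0
    c_mbr: float = 2.0
    tau: float = 5.0
    t_refractory: float = 2.2
    t_dly: float = 1.8
    w_syn: float = 0.275

    def __post_init__(self) -> None:
        if self.v_reset > self.v_threshold:
            raise ValueError("v_reset must not exceed v_threshold")
        if self.v_resting >= self.v_threshold:
            raise ValueError("v_resting must lie below v_threshold")
        for name in ("r_mbr", "c_mbr", "tau", "t_refractory", "t_dly"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isfinite(self.w_syn):
            raise ValueError("w_syn must be finite")

    @property
    def t_mbr(self) -> float:
        """Membrane time constant (ms), recomputed as R*C."""
        return self.r_mbr * self.c_mbr

    def replace(self, **changes) -> "LIFParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t_mbr"] = self.t_mbr
        return d


DEFAULT_PARAMS = LIFParameters()
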