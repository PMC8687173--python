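"""Physiological parameter sets for the glucose-insulin meal homoeostasis model.

Two built-in cohorts are shipped: ``"normal"`` (healthy adult, 78 kg) and
``"t2dm"`` (type 2 diabetes mellitus, 91 kg).  Every field can be overridden
individually, e.g. ``ModelParameters.from_profile("normal", kabs=0.04)``.

Units follow the compartmental convention: glucose masses per kg body weight
(mg/kg), insulin masses per kg (pmol/kg), concentrations in mg/dl (glucose)
and pmol/l (insulin), rate constants in 1/min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

__all__ = ["ModelParameters", "PROFILES", "STATE_NAMES", "GP_INDEX"]

#: State ordering used everywhere: x = [Qsto1, Qsto2, Qgut, Gp, Y, Ipo,
#: Id, I1, Il, Ip, Gt, X].
STATE_NAMES = (
    "Qsto1",  # mg, solid glucose in stomach
    "Qsto2",  # mg, liquid glucose (chyme) in stomach
    "Qgut",   # mg, glucose in intestine
    "Gp",     # mg/kg, plasma glucose mass
    "Y",      # pmol/kg/min, new (provisioned) insulin production
    "Ipo",    # pmol/kg, portal-vein insulin mass
    "Id",     # pmol/l, delayed insulin signal
    "I1",     # pmol/l, first insulin-delay compartment
    "Il",     # pmol/kg, liver insulin mass
    "Ip",     # pmol/kg, plasma insulin mass
    "Gt",     # mg/kg, tissue glucose mass
    "X",      # pmol/l, interstitial insulin action
)

#: Index of the measured state (plasma glucose mass) in STATE_NAMES.
GP_INDEX = STATE_NAMES.index("Gp")

#: States that are physical masses/concentrations and are clipped at zero
#: during integration; Y and X may be transiently negative.
NONNEGATIVE_STATES = tuple(i for i, s in enumerate(STATE_NAMES) if s not in ("Y", "X"))


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, volumes and basal values for one cohort.

    Attributes
    ----------
    cohort : str
        ``"normal"`` or ``"t2dm"`` (or ``"custom"`` for overridden sets).
    VG : float
        Glucose distribution volume, dl/kg.
    Gb : float
        Basal plasma glucose concentration, mg/dl.  Also the glucose
        threshold ``h`` of the beta-cell responsivity.
    k1, k2 : float
        Plasma<->tissue glucose transfer rates, 1/min.
    VI : float
        Insulin distribution volume, l/kg.
    Ib : float
        Basal plasma insulin concentration, pmol/l.
    m1, m2, m4 : float
        Insulin transfer/degradation rates, 1/min.
    m3_basal : float
        Basal liver insulin degradation rate, 1/min (consistency check only;
        the dynamic m3 follows the hepatic extraction).
    m5 : float
        min*kg/pmol, slope of hepatic extraction vs secretion.
    m6 : float
        Dimensionless intercept of hepatic extraction vs secretion.
    HEb : float
        Basal hepatic insulin extraction fraction (0.6 in both cohorts).
    Sb : float
        Basal insulin secretion, pmol/kg/min.
    kmax, kmin, kabs, kgri : float
        Gastric emptying bounds, intestinal absorption and grinding rates,
        1/min.
    f : float
        Fraction of absorbed glucose appearing in plasma.
    b, c : float
        Dimensionless shape fractions of the gastric emptying curve (b > c).
    kp1 : float
        Extrapolated endogenous glucose production at zero glucose and
        insulin, mg/kg/min.
    kp2, kp3, kp4, ki : float
        EGP suppression gains and the insulin-signal delay rate.
    EGPb : float
        Basal endogenous glucose production, mg/kg/min (tabulated; cross-
        checked against the linear EGP form at the basal point).
    Fcns : float
        Insulin-independent utilisation (brain, erythrocytes), mg/kg/min.
    Vm0, Vmx, Km0, Kmx, p2u : float
        Insulin-dependent (Michaelis-Menten) utilisation parameters.
    K, A, B, gamma : float
        Beta-cell secretion parameters: pancreatic responsiveness to the
        glucose rate of change, responsivity dynamics, static responsivity,
        and portal-vein insulin turnover.
    ke1, ke2 : float
        Renal excretion rate (1/min) and renal threshold (mg/kg of Gp).
    BW : float
        Body weight, kg.
    """

    cohort: str
    # glucose kinetics
    VG: float
    Gb: float
    k1: float
    k2: float
    # insulin kinetics
    VI: float
    Ib: float
    m1: float
    m2: float
    m3_basal: float
    m4: float
    m5: float
    m6: float
    HEb: float
    Sb: float
    # rate of appearance
    kmax: float
    kmin: float
    kabs: float
    kgri: float
    f: float
    b: float
    c: float
    # endogenous glucose production
    kp1: float
    kp2: float
    kp3: float
    kp4: float
    ki: float
    EGPb: float
    # utilisation
    Fcns: float
    Vm0: float
    Vmx: float
    Km0: float
    Kmx: float
    p2u: float
    # secretion
    K: float
    A: float
    B: float
    gamma: float
    # renal elimination
    ke1: float
    ke2: float
    BW: float

    def __post_init__(self) -> None:
        positive = (
            "VG Gb k1 k2 VI Ib m1 m2 m3_basal m4 m5 kmax kmin kabs kgri "
            "kp1 ki EGPb Fcns Vm0 Km0 p2u K A B gamma ke1 ke2 BW Sb"
        ).split()
        bad = [name for name in positive if getattr(self, name) <= 0]
        for name in ("kp2", "kp3", "kp4", "Vmx", "Kmx", "m6"):
            if getattr(self, name) < 0:
                bad.append(name)
        for name in ("f", "b", "c", "HEb"):
            if not 0 < getattr(self, name) < 1:
                bad.append(name)
        if self.b <= self.c:
            bad.append("b<=c")
        if self.kmax < self.kmin:
            bad.append("kmax<kmin")
        if bad:
            raise ValueError(f"invalid parameter values: {', '.join(sorted(set(bad)))}")
        # Basal consistency of the hepatic-extraction chain: HEb = m6 - m5*Sb.
        if abs(self.HEb - (self.m6 - self.m5 * self.Sb)) >= 1e-3:
            raise ValueError(
                "inconsistent basal secretion: HEb must equal m6 - m5*Sb within 1e-3"
            )

    @classmethod
    def from_profile(cls, cohort: str, **overrides: float) -> "ModelParameters":
        """Return a built-in cohort parameter set, optionally overridden."""
        try:
            base = PROFILES[cohort]
        except KeyError:
            raise KeyError(
                f"unknown cohort {cohort!r}; available: {sorted(PROFILES)}"
            ) from None
        unknown = set(overrides) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown parameter fields: {sorted(unknown)}")
        return dataclasses.replace(base, **overrides) if overrides else base

    @classmethod
    def normal(cls, **overrides: float) -> "ModelParameters":
        return cls.from_profile("normal", **overrides)

    @classmethod
    def t2dm(cls, **overrides: float) -> "ModelParameters":
        return cls.from_profile("t2dm", **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParameters":
        return cls(**d)


PROFILES: dict[str, ModelParameters] = {
    "normal": ModelParameters(
        cohort="normal",
        VG=1.88, Gb=75.177, k1=0.065, k2=0.079,
        VI=0.05, Ib=25.556,
        m1=0.190, m2=0.484, m3_basal=0.285, m4=0.194,
        m5=0.0304, m6=0.6471, HEb=0.6, Sb=1.549,
        kmax=0.0558, kmin=0.008, kabs=0.057, kgri=0.0558,
        f=0.9, b=0.82, c=0.01,
        kp1=2.7, kp2=0.0021, kp3=0.009, kp4=0.0618, ki=0.0079, EGPb=1.8,
        Fcns=1.0, Vm0=2.5, Vmx=0.047, Km0=225.59, Kmx=0.0, p2u=0.0331,
        K=2.3, A=0.05, B=0.11, gamma=0.5,
        ke1=0.0005, ke2=339.0, BW=78.0,
    ),
    "t2dm": ModelParameters(
        cohort="t2dm",
        VG=1.49, Gb=181.4737, k1=0.042, k2=0.071,
        VI=0.04, Ib=59.875,
        m1=0.379, m2=0.673, m3_basal=0.5685, m4=0.269,
        m5=0.0526, m6=0.8118, HEb=0.6, Sb=4.027,
        kmax=0.0465, kmin=0.0076, kabs=0.023, kgri=0.0465,
        f=0.9, b=0.68, c=0.09,
        kp1=3.09, kp2=0.0007, kp3=0.005, kp4=0.0786, ki=0.0066, EGPb=2.1,
        Fcns=1.0, Vm0=4.65, Vmx=0.034, Km0=466.21, Kmx=0.0, p2u=0.0840,
        K=0.99, A=0.013, B=0.05, gamma=0.5,
        ke1=0.0007, ke2=269.0, BW=91.0,
    ),
}
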