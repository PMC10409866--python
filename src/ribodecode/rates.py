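"""Rate constants and photophysical parameters of the decoding system.

The decoding cycle of an aminoacyl-tRNA (delivered as the ternary complex
EF-Tu–GTP–aa-tRNA) is parameterized by a set of elemental rate constants:
initial binding (k1, k-1), codon recognition (k2, k-2), GTPase activation +
GTP hydrolysis (lumped k_gtp), post-hydrolysis rearrangement / Pi release
(k4), accommodation (k5), drop-off (k7), peptide bond formation (k_pep) and
the classical<->hybrid (A/A, A/P <-> A/P*) fluctuation rates of the
peptidyl-tRNA after peptide bond formation.  All rates are apparent
first-order rates in s^-1; bimolecular association is folded into the
pseudo-first-order k1_app at the stated ternary-complex concentration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "RateSet",
    "FRETMap",
    "CameraModel",
    "REFERENCE_RATES",
    "load_ratesets",
    "dump_ratesets",
    "channel_noise_for_fret_sd",
]


_RATE_FIELDS = (
    "k1_app",
    "k_rev1",
    "k2",
    "k_rev2",
    "k_gtp",
    "k4",
    "k5",
    "k7",
    "k_pep",
    "k6",
    "k_hyb_fwd",
    "k_hyb_rev",
    "k5b",
    "k_slow",
)


@dataclass
class RateSet:
    """Named per-codon rate constants of the decoding scheme (s^-1).

    ``k1_app`` is the pseudo-first-order association rate k1*[TC] at the
    working ternary-complex concentration.  ``k_gtp`` lumps GTPase
    activation and GTP hydrolysis; ``k4``/``k5`` form the post-hydrolysis
    accommodation path (their series composite is used unless the two-step
    variant is requested).  ``k5b``/``k_slow`` optionally enable a second,
    slower accommodation route (heterogeneous accommodation gives visibly
    biphasic product-formation kinetics).  Setting ``k_gtp = 0`` encodes
    the GTPase-deficient (H84A-type) protocol in which nothing beyond the
    codon-reading state is reachable.
    """

    k1_app: float = 0.7
    k_rev1: float = 8.1
    k2: float = 30.0
    k_rev2: float = 0.34
    k_gtp: float = 25.0
    k4: float = 8.0
    k5: float = 8.0
    k7: float = 0.1
    k_pep: float = 5.0
    k6: float = 0.0  # EF-Tu release; folded into accommodation by default
    k_hyb_fwd: float = 2.9
    k_hyb_rev: float = 4.4
    k5b: float = 0.0  # slow accommodation route (0 = disabled)
    k_slow: float = 0.0  # entry rate into the slow route
    label: str = ""

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name!r} must be finite and >= 0, got {value!r}")

    @property
    def k_acc(self) -> float:
        """Effective single-rate POST_GTP -> accommodated composite.

        Series of k4 then k5 collapsed to one exponential with the same
        mean passage time (1/k4 + 1/k5).
        """
        if self.k4 <= 0 or self.k5 <= 0:
            return 0.0
        return 1.0 / (1.0 / self.k4 + 1.0 / self.k5)

    def replace(self, **kwargs) -> "RateSet":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in _RATE_FIELDS}
        d["label"] = self.label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        known = set(_RATE_FIELDS) | {"label"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        return cls(**d)


#: Reference rate sets for decoding of the unmodified AAA codon and the
#: N6-methyladenosine-modified m6AAA codon.  The dissociation rates
#: (k_rev1, k_rev2) and the hybrid-state fluctuation rates are the
#: single-molecule measurements for these codons; the remaining forward
#: rates are nominal defaults on the measured apparent-rate scale (the
#: elemental forward constants are not individually constrained for these
#: codons) and are declared as such in the documentation.
REFERENCE_RATES: dict[str, RateSet] = {
    "AAA": RateSet(
        k1_app=0.7,
        k_rev1=8.1,
        k2=30.0,
        k_rev2=0.34,
        k_gtp=25.0,
        k4=8.0,
        k5=8.0,
        k7=0.1,
        k_pep=5.0,
        k_hyb_fwd=2.9,
        k_hyb_rev=4.4,
        label="AAA",
    ),
    "m6AAA": RateSet(
        k1_app=0.7,
        k_rev1=15.0,
        k2=30.0,
        k_rev2=1.1,
        k_gtp=3.0,
        k4=2.0,
        k5=2.0,
        k7=0.3,
        k_pep=5.0,
        k_hyb_fwd=2.8,
        k_hyb_rev=4.2,
        label="m6AAA",
    ),
}


@dataclass
class FRETMap:
    """Mean FRET efficiency and Gaussian width per mechanistic state.

    The donor sits on ribosomal protein L11, the acceptor on the incoming
    tRNA elbow: no FRET while unbound, ~0.9 during initial binding /
    codon reading, ~0.8 in the classical A/A, A/P states and ~0.6 in the
    hybrid A/P* state.
    """

    means: dict[str, float] = field(
        default_factory=lambda: {
            "UNBOUND": 0.0,
            "IB": 0.9,
            "CR": 0.9,
            "POST_GTP": 0.9,
            "ACCOMMODATED_CLASSICAL": 0.8,
            "HYBRID_APstar": 0.6,
            "DROPPED": 0.0,
        }
    )
    sds: dict[str, float] = field(default_factory=dict)
    default_sd: float = 0.05

    def __post_init__(self) -> None:
        for state, mu in self.means.items():
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"FRET mean for {state} outside [0, 1]: {mu}")
        for state, sd in self.sds.items():
            if sd <= 0:
                raise ValueError(f"FRET s.d. for {state} must be > 0: {sd}")

    def mean(self, state: str) -> float:
        return self.means[state]

    def sd(self, state: str) -> float:
        return self.sds.get(state, self.default_sd)

    @property
    def levels(self) -> dict[str, float]:
        """Distinct named FRET levels used for dwell/state assignment."""
        lv = {"dark": 0.0}
        high = [self.means[s] for s in ("IB", "CR", "POST_GTP") if s in self.means]
        if high:
            lv["high"] = float(sum(high) / len(high))
        if "ACCOMMODATED_CLASSICAL" in self.means:
            lv["classical"] = self.means["ACCOMMODATED_CLASSICAL"]
        if "HYBRID_APstar" in self.means:
            lv["hybrid"] = self.means["HYBRID_APstar"]
        return lv


def channel_noise_for_fret_sd(fret_sd: float, at_fret: float = 0.9, total_intensity: float = 1.0) -> float:
    """Per-channel Gaussian read-noise s.d. yielding a given FRET width.

    With donor = I(1-E) + eps_d and acceptor = I*E + eps_a, the computed
    efficiency a/(a+d) has, to first order, s.d.
    (sigma/I) * sqrt(E^2 + (1-E)^2).  Inverting gives the channel noise
    needed so that a state at efficiency ``at_fret`` shows the requested
    apparent width.
    """
    if fret_sd <= 0:
        raise ValueError("fret_sd must be > 0")
    geom = math.sqrt(at_fret**2 + (1.0 - at_fret) ** 2)
    return fret_sd * total_intensity / geom


@dataclass
class CameraModel:
    """Acquisition and photophysics parameters of the TIRF recording.

    frame_rate    frames per second (default 30.3)
    total_intensity   summed two-channel intensity of one molecule (a.u.)
    noise_sd      Gaussian read noise s.d. per channel (a.u.); the default
                  makes a high-FRET state appear with width ~0.05 in E
    bleedthrough  donor -> acceptor bleed-through coefficient beta
    window_s      observation window T (s)
    k_photobleach single-step photobleaching rate (s^-1)
    """

    frame_rate: float = 30.3
    total_intensity: float = 1.0
    noise_sd: float = channel_noise_for_fret_sd(0.05)
    bleedthrough: float = 0.13
    window_s: float = 33.0
    k_photobleach: float = 0.03

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 <= self.bleedthrough < 1.0:
            raise ValueError("bleedthrough must be in [0, 1)")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.k_photobleach < 0:
            raise ValueError("k_photobleach must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.window_s * self.frame_rate))

    def replace(self, **kwargs) -> "CameraModel":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "total_intensity": self.total_intensity,
            "noise_sd": self.noise_sd,
            "bleedthrough": self.bleedthrough,
            "window_s": self.window_s,
            "k_photobleach": self.k_photobleach,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(**d)


def load_ratesets(path) -> dict[str, RateSet]:
    """Read rate sets from a YAML config: one section per codon label."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for label, section in raw.items():
        section = dict(section)
        section.setdefault("label", label)
        out[label] = RateSet.from_dict(section)
    return out


def dump_ratesets(ratesets: dict[str, RateSet], path) -> None:
    """Write rate sets to YAML; round-trip stable with :func:`load_ratesets`."""
    payload = {label: rs.to_dict() for label, rs in ratesets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
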