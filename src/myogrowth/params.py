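"""Parameter containers and configuration I/O.

Every default below is a published model constant: the biochemical
(Lotka-Volterra) rates and thresholds, the hyperelastic material constants,
the reference fusiform geometry, the training protocol (24 one-hour sessions
on days 1, 3 and 5 of each week for 8 weeks at 80% of the one-repetition
maximum) and the activation-feedback constants.  Configurations round-trip
through plain dictionaries and JSON/TOML/YAML files so that every experiment
is reproducible from a single config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

__all__ = [
    "KGF_TO_N",
    "MPA_CM2_TO_N",
    "CM2_TO_M2",
    "PathwayParameters",
    "PathwayState",
    "StimulusParameters",
    "MaterialParameters",
    "FeedbackParameters",
    "ProtocolConfig",
    "initial_state",
    "SimulationConfig",
    "default_config",
    "load_config",
    "dump_config",
    "config_hash",
]

#: 1 kilogram-force in newtons (standard gravity).
KGF_TO_N = 9.80665
#: 1 MPa acting on 1 cm^2, in newtons.
MPA_CM2_TO_N = 100.0
#: square centimetres to square metres.
CM2_TO_M2 = 1.0e-4


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass
class PathwayParameters:
    """Rate constants of the IGF1-AKT-mTOR-FOXO population model.

    Units: intrinsic rates ``a*`` and synthesis/degradation rates ``k1``/``k2``
    in 1/hour; self-inhibition ``b*`` and couplings ``c*`` in 1/(hour a.u.);
    populations, bounds and thresholds in arbitrary units (a.u.).
    """

    a10: float = 9.000e-2  # resting IGF1 intrinsic growth rate
    a20: float = 4.875e-1  # resting AKT intrinsic growth rate
    a3: float = 1.068e-2   # FOXO intrinsic growth rate
    a4: float = 4.635e-3   # mTOR intrinsic growth rate
    b1: float = 2.000e0
    b2: float = 5.000e-1
    b3: float = 2.000e-2
    b4: float = 1.000e-2
    c21: float = 2.846e-1  # IGF1 -> AKT activation
    c32: float = 2.000e-3  # AKT -| FOXO inhibition
    c42: float = 1.139e-3  # AKT -> mTOR activation
    c43: float = 2.500e-3  # FOXO -| mTOR inhibition
    z_min: float = 0.5     # minimum myofibril population
    z_max: float = 1.3     # maximum myofibril population
    x3_thr: float = 4.340e-1  # FOXO threshold (degradation engages above)
    x4_thr: float = 4.690e-1  # mTOR threshold (synthesis engages above)
    k1: float = 2.500e-2   # protein-synthesis rate
    k2: float = 1.900e-2   # protein-degradation rate

    def __post_init__(self) -> None:
        for name in ("a10", "a20", "a3", "a4", "b1", "b2", "b3", "b4",
                     "c21", "c32", "c42", "c43", "k1", "k2"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.z_min < self.z_max, "z_min must be below z_max")
        _require(0 < self.x3_thr < 1, "x3_thr must lie in (0, 1)")
        _require(0 < self.x4_thr < 1, "x4_thr must lie in (0, 1)")


@dataclass
class PathwayState:
    """Instantaneous state of the biochemical system.

    ``x1``..``x4`` are the IGF1, AKT, FOXO and mTOR populations, ``z`` the
    myofibril population (all a.u.), ``t`` in hours.  ``a2_cur`` tracks the
    current value of the pulsed AKT intrinsic rate a2(t).
    """

    t: float
    x1: float
    x2: float
    x3: float
    x4: float
    z: float
    a2_cur: float = 4.875e-1

    def populations(self) -> tuple[float, float, float, float]:
        return (self.x1, self.x2, self.x3, self.x4)


def initial_state(pathway: Optional[PathwayParameters] = None) -> PathwayState:
    """Published initial conditions (homeostatic concentrations normalized
    to IGF1; myofibril population set to one)."""
    a20 = pathway.a20 if pathway is not None else 4.875e-1
    return PathwayState(t=0.0, x1=1.000e-2, x2=9.880e-1, x3=4.318e-1,
                        x4=4.692e-1, z=1.000e0, a2_cur=a20)


@dataclass
class StimulusParameters:
    """Exercise input signals a1(t) and a2(t).

    ``stim_gain`` is the 2/50 (hour kgf)^-1 gain of the training input;
    during a session a1 = stim_gain * intensity * f_max, otherwise a1 = a10.
    After each session start the AKT rate a2 follows a 17-hour pulse with
    decay constant ``tau_h`` = 6 h, then returns to ``a20``.
    """

    stim_gain: float = 2.0 / 50.0          # 1/(hour kgf)
    intensity: float = 0.8                 # fraction of 1-RM
    f_max: Optional[float] = None          # kgf; measured from the structure when None
    tau_h: float = 6.0                     # hours
    t1_pulse: float = 17.0                 # hours
    a10: float = 9.000e-2                  # resting a1
    a20: float = 4.875e-1                  # resting a2

    def __post_init__(self) -> None:
        # zero intensity is a well-defined degenerate (unloaded) session
        _require(0 <= self.intensity <= 1, "intensity must lie in [0, 1]")
        _require(self.tau_h > 0, "tau_h must be positive")
        _require(self.t1_pulse > 0, "t1_pulse must be positive")


@dataclass
class MaterialParameters:
    """Transversely isotropic hyperelastic constants (energies in MPa).

    ``inv_D`` is the bulk-like modulus 1/D of the volumetric term
    (1/D)(J-1)^2; ``c1`` the neo-Hookean matrix modulus; ``c3``/``c4`` the
    exponential collagen term with uncurling stretch invariant
    ``I4_uncurl``; ``sigma_o`` the maximum isometric tension scale;
    ``lambda_opt``/``alpha`` shape the active force-stretch relation.
    """

    inv_D: float = 100.0
    c1: float = 0.0100
    c3: float = 0.0543
    c4: float = 6.86
    I4_uncurl: float = 1.2544
    sigma_o: float = 0.100
    lambda_opt: float = 1.000
    alpha: float = 0.83616

    def __post_init__(self) -> None:
        for name in ("inv_D", "c1", "c3", "c4", "sigma_o"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")
        _require(0 < self.alpha < 1, "alpha must lie in (0, 1)")
        _require(self.I4_uncurl >= 1, "I4_uncurl must be >= 1")


@dataclass
class FeedbackParameters:
    """Mechano-to-biochemical feedback on the protein-synthesis rate.

    Modes: ``"baseline"`` keeps k1 = k10; ``"beta"`` applies
    k1 = k10 (d1 beta_req - d2) with the required activation beta_req for the
    fixed training load; ``"linear"`` applies the straight-line surrogate
    k1 = k10 (b - m A) with the CSA ``A`` in m^2.  k1 is floored at zero.
    When ``intercept_b`` is None it is chosen so that k1/k10 at the initial
    CSA matches the beta-feedback value there (d1 - d2).
    """

    d1: float = 20.40
    d2: float = 18.907
    k10: float = 2.500e-2
    mode: str = "beta"
    slope_m: float = 3440.0        # per m^2, linear mode
    intercept_b: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.mode in ("baseline", "beta", "linear"),
                 f"unknown feedback mode {self.mode!r}")
        _require(self.d1 > self.d2 >= 0, "require d1 > d2 >= 0")
        _require(self.k10 > 0, "k10 must be positive")


@dataclass
class ProtocolConfig:
    """Training schedule and numerical resolution.

    The default reproduces the published protocol: 24 one-hour sessions on
    days 1, 3 and 5 of every week over 8 weeks at 80% of the 1-RM, a
    biochemical step ``dt`` = 0.05 h and a growth step ``dt_growth`` = 1 h.
    Setting ``every_n_days`` replaces the weekly day pattern with a fixed
    inter-session interval (used by the training-frequency scan).
    """

    session_days: Sequence[int] = (1, 3, 5)
    every_n_days: Optional[int] = None
    session_hours: float = 1.0
    n_sessions: Optional[int] = None    # None: fill the whole protocol
    intensity: float = 0.8
    total_weeks: int = 8
    dt: float = 0.05                    # hours
    dt_growth: float = 1.0              # hours
    kappa_ratio: float = 1.0            # kappa / kappa0 with kappa0 = z(0)/A(0)

    def __post_init__(self) -> None:
        self.session_days = tuple(self.session_days)
        _require(self.dt > 0 and self.dt_growth > 0, "time steps must be positive")
        ratio = self.dt_growth / self.dt
        _require(abs(ratio - round(ratio)) < 1e-9,
                 "dt_growth must be an integer multiple of dt")
        _require(0 < self.intensity <= 1, "intensity must lie in (0, 1]")
        _require(self.total_weeks > 0, "total_weeks must be positive")
        _require(self.kappa_ratio > 0, "kappa_ratio must be positive")
        if self.every_n_days is None:
            _require(all(1 <= d <= 7 for d in self.session_days),
                     "session_days must be days 1..7 of the week")
            _require(len(set(self.session_days)) == len(self.session_days),
                     "session_days must be distinct")
        else:
            _require(self.every_n_days >= 1, "every_n_days must be >= 1")

    @property
    def total_hours(self) -> float:
        return self.total_weeks * 7 * 24.0

    @classmethod
    def every_n(cls, n_days: int, **kwargs: Any) -> "ProtocolConfig":
        """Protocol training every ``n_days`` days (daily for 1)."""
        return cls(every_n_days=n_days, **kwargs)


# ---------------------------------------------------------------------------
# whole-simulation configuration


@dataclass
class SimulationConfig:
    """Bundle of every configuration block of one simulation."""

    pathway: PathwayParameters = field(default_factory=PathwayParameters)
    stimulus: StimulusParameters = field(default_factory=StimulusParameters)
    material: MaterialParameters = field(default_factory=MaterialParameters)
    feedback: FeedbackParameters = field(default_factory=FeedbackParameters)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    # reference geometry (fusiform): length, mid-belly and end diameters, cm
    length0: float = 20.0
    diam_mid: float = 6.5
    diam_end: float = 2.34

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        kwargs: dict[str, Any] = {}
        blocks = {
            "pathway": PathwayParameters,
            "stimulus": StimulusParameters,
            "material": MaterialParameters,
            "feedback": FeedbackParameters,
            "protocol": ProtocolConfig,
        }
        for key, value in data.items():
            if key in blocks:
                kwargs[key] = blocks[key](**value)
            elif key in ("length0", "diam_mid", "diam_end"):
                kwargs[key] = float(value)
            else:
                raise ValueError(f"unknown configuration block {key!r}")
        return cls(**kwargs)


def default_config() -> SimulationConfig:
    """The published study conditions, as a fresh configuration."""
    return SimulationConfig()


def load_config(path: str | Path) -> SimulationConfig:
    """Read a configuration from a JSON, TOML or YAML file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    elif suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        data = json.loads(path.read_text())
    return SimulationConfig.from_dict(data)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as JSON (the canonical on-disk form)."""
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))


def config_hash(config: SimulationConfig) -> str:
    """Deterministic short hash identifying a configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
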