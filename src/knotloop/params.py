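"""Model and protocol parameter containers.

Everything is expressed in reduced (Lennard-Jones) units: the bead diameter
``sigma`` is the unit of length, the WCA well depth ``epsilon`` the unit of
energy, the bead mass ``m`` the unit of mass, and ``tau = sigma*sqrt(m/epsilon)``
the unit of time.  The thermal energy is ``kbt = epsilon`` unless stated
otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Tuple

import yaml

__all__ = ["ModelParams", "RunProtocol", "WCA_CUTOFF_FACTOR", "ConfigError"]

#: r_min of the 12-6 potential; the WCA cutoff and the peak of the sticky well.
WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


class ConfigError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Force-field constants and adhesive-site layout of one chain.

    The chain is a Kremer-Grest bead-spring polymer: WCA excluded volume
    between all bead pairs, FENE springs between consecutive beads, an
    optional harmonic-angle bending stiffness, and short-ranged Gaussian
    adhesion between (at most) two designated bead pairs: the termini
    (which circularize the chain) and one internal pair (which closes the
    sticky loop).

    Parameters
    ----------
    n_beads
        Number of beads N.
    kappa_bend
        Bending stiffness in units of energy; 0 selects the fully flexible
        (L-DNA) regime, ``10*kbt`` the semiflexible (S-DNA) regime.
    sticky_terminal_pair
        Bead indices of the circularizing pair, ``(0, N-1)`` when present.
    sticky_internal_pair
        Bead indices ``(x, y)`` of the internal adhesive pair, strictly
        inside the chain, or ``None`` for a reference chain without a
        sticky loop.
    """

    n_beads: int
    sigma: float = 1.0
    epsilon: float = 1.0
    mass: float = 1.0
    kappa_fene: float = 30.0
    r0_fene: float = 1.5
    u0_sticky: float = 100.0
    lambda_sticky: float = 2.5
    kappa_bend: float = 0.0
    kbt: float = 1.0
    sticky_terminal_pair: Optional[Tuple[int, int]] = None
    sticky_internal_pair: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.n_beads < 4:
            raise ConfigError("n_beads must be >= 4")
        for name in ("sigma", "epsilon", "mass", "kbt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.r0_fene <= WCA_CUTOFF_FACTOR * self.sigma:
            raise ConfigError("r0_fene must exceed the WCA minimum 2^(1/6)*sigma")
        if self.kappa_bend < 0:
            raise ConfigError("kappa_bend must be >= 0")
        tp = self.sticky_terminal_pair
        if tp is not None and tuple(tp) != (0, self.n_beads - 1):
            raise ConfigError("sticky_terminal_pair must be (0, N-1)")
        ip = self.sticky_internal_pair
        if ip is not None:
            x, y = ip
            if not (0 < x < y < self.n_beads - 1):
                raise ConfigError(
                    "internal sticky pair must be strictly inside the chain, x < y"
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def chain(
        cls,
        n_beads: int,
        *,
        regime: str = "L",
        internal_pair: Optional[Tuple[int, int]] = None,
        terminal: bool = True,
        **kwargs,
    ) -> "ModelParams":
        """Build the standard chain of either stiffness regime.

        ``regime='L'`` is the flexible chain (``kappa_bend = 0``);
        ``regime='S'`` the semiflexible one (``kappa_bend = 10*kbt``).
        """
        kbt = kwargs.pop("kbt", 1.0)
        if regime == "L":
            kappa_bend = 0.0
        elif regime == "S":
            kappa_bend = 10.0 * kbt
        else:
            raise ConfigError(f"unknown regime {regime!r} (expected 'L' or 'S')")
        return cls(
            n_beads=n_beads,
            kappa_bend=kappa_bend,
            kbt=kbt,
            sticky_terminal_pair=(0, n_beads - 1) if terminal else None,
            sticky_internal_pair=internal_pair,
            **kwargs,
        )

    @property
    def wca_cutoff(self) -> float:
        return WCA_CUTOFF_FACTOR * self.sigma

    @property
    def sticky_outer_cutoff(self) -> float:
        return (WCA_CUTOFF_FACTOR + 5.0) * self.sigma

    @property
    def regime(self) -> str:
        return "L" if self.kappa_bend == 0 else "S"

    # -- serialization ------------------------------------------------------------

    def to_config(self) -> dict:
        """Flat key/value mapping (reduced units) suitable for a YAML file."""
        d = asdict(self)
        for key in ("sticky_terminal_pair", "sticky_internal_pair"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_config(cls, d: dict) -> "ModelParams":
        d = dict(d)
        for key in ("sticky_terminal_pair", "sticky_internal_pair"):
            if d.get(key) is not None:
                d[key] = tuple(int(v) for v in d[key])
        return cls(**d)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RunProtocol:
    """Integration and termination settings for one Langevin run.

    ``dt`` is the integration timestep (units of tau), ``gamma`` the friction
    rate of the Langevin thermostat (1/tau), ``capture_distance`` the
    separation at which an adhesive pair bonds permanently, and ``max_steps``
    the censoring cap for runs that never circularize.
    """

    dt: float = 0.005
    gamma: float = 0.1
    capture_distance: float = 1.3
    max_steps: int = 1_000_000_000
    seed: int = 0
    snapshot_interval: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if self.capture_distance < WCA_CUTOFF_FACTOR:
            raise ConfigError("capture_distance must be >= 2^(1/6)*sigma")
        if self.max_steps <= 0:
            raise ConfigError("max_steps must be positive")

    def to_config(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, d: dict) -> "RunProtocol":
        return cls(**d)

    def replace(self, **kwargs) -> "RunProtocol":
        return replace(self, **kwargs)


def config_hash(params: ModelParams, protocol: RunProtocol) -> str:
    """Short stable hash identifying a (model, protocol) combination."""
    blob = json.dumps(
        {"model": params.to_config(), "protocol": protocol.to_config()},
        sort_keys=True,
    )
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def save_config(path, params: ModelParams, protocol: RunProtocol, **extra) -> None:
    doc = {"model": params.to_config(), "protocol": protocol.to_config()}
    doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> Tuple[ModelParams, RunProtocol, dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        params = ModelParams.from_config(doc["model"])
        protocol = RunProtocol.from_config(doc["protocol"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    extra = {k: v for k, v in doc.items() if k not in ("model", "protocol")}
    return params, protocol, extra
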