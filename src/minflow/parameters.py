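"""Kinetic parameter sets and the named-set registry.

Units convention
----------------
The vertical bulk dimension is integrated out, so bulk concentrations are
areal densities (1/μm²) and the bulk-height factor is absorbed into the
attachment rate constants:

* ``k_D``      basal MinD attachment, 1/s (bulk areal density → membrane)
* ``k_dD``     MinD self-recruitment, μm²/s
* ``k_dEr``    recruitment of reactive MinE by membrane MinD, μm²/s
* ``k_dEi``    recruitment of latent MinE by membrane MinD, μm²/s
* ``k_de``     MinDE complex detachment (hydrolysis), 1/s
* ``lambda_``  nucleotide exchange ADP→ATP in the bulk, 1/s
* ``mu``       MinE conformational switching reactive→latent, 1/s
* ``D_m``      membrane diffusivity, μm²/s
* ``D_c``      bulk (lateral) diffusivity, μm²/s
* ``v_f``      bulk flow velocity, μm/s, signed; +x is downstream
* ``n_D_mean``, ``n_E_mean``  mean total densities, 1/μm²

Every run names its parameter set so results are reproducible; use
:func:`get_parameter_set` and override fields with
:meth:`KineticParameters.with_`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import yaml

VARIANTS = ("full", "skeleton", "reduced_switch")


@dataclass(frozen=True)
class KineticParameters:
    """All rates, diffusivities, flow velocity and total densities for one
    model variant (see module docstring for units)."""

    k_D: float
    k_dD: float
    k_dEr: float
    k_dEi: float
    k_de: float
    lambda_: float
    mu: float
    D_m: float
    D_c: float
    v_f: float
    n_D_mean: float
    n_E_mean: float
    variant: str = "full"
    advect_minE: bool = True
    name: str = "unnamed"

    def __post_init__(self):
        for f in ("k_D", "k_dD", "k_dEr", "k_dEi", "k_de", "lambda_", "mu",
                  "D_m", "D_c"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.n_D_mean <= 0:
            raise ValueError("n_D_mean must be positive")
        if self.n_E_mean < 0:
            raise ValueError("n_E_mean must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "skeleton" and self.mu != 0.0:
            raise ValueError("skeleton variant requires mu = 0")

    @property
    def ed_ratio(self) -> float:
        """Total MinE:MinD density ratio, the main control parameter."""
        return self.n_E_mean / self.n_D_mean

    def with_(self, **kw) -> "KineticParameters":
        """Return a copy with the given fields replaced.

        ``ed_ratio=r`` is accepted as a shorthand for
        ``n_E_mean = r * n_D_mean``.
        """
        kw = dict(kw)
        if "ed_ratio" in kw:
            r = kw.pop("ed_ratio")
            kw["n_E_mean"] = r * kw.get("n_D_mean", self.n_D_mean)
        if kw.get("variant", self.variant) == "skeleton":
            kw.setdefault("mu", 0.0)
            if kw.get("mu", 0.0) != 0.0:
                raise ValueError("skeleton variant requires mu = 0")
        return dataclasses.replace(self, **kw)

    def skeleton(self) -> "KineticParameters":
        """The no-switch reduction: mu = 0 and all bulk MinE reactive."""
        return self.with_(variant="skeleton", mu=0.0)

    def items(self) -> Iterator[tuple[str, object]]:
        for f in dataclasses.fields(self):
            yield f.name, getattr(self, f.name)

    # -- flat key:value persistence ------------------------------------

    def to_dict(self) -> dict:
        return {k: v for k, v in self.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Registry.
#
# "denk2d" is the package default: the MinE-switch reaction scheme with rate
# constants adapted from the Denk et al. switch model to the 2D
# bulk-integrated geometry (bulk height absorbed into attachment rates, see
# module docstring), with total densities giving in vitro-like wavelengths
# of tens of μm and wave speeds of hundreds of nm/s.
# ---------------------------------------------------------------------------

PARAMETER_SETS: dict[str, KineticParameters] = {}


def _register(p: KineticParameters) -> KineticParameters:
    PARAMETER_SETS[p.name] = p
    return p


DENK2D = _register(KineticParameters(
    name="denk2d",
    k_D=0.0004,
    k_dD=0.002,
    k_dEr=0.055,
    k_dEi=0.0014,
    k_de=0.27,
    lambda_=0.08,
    mu=2.8,
    D_m=0.18,
    D_c=65.0,
    v_f=0.0,
    n_D_mean=2500.0,
    n_E_mean=500.0,
    variant="full",
))


def get_parameter_set(name: str, **overrides) -> KineticParameters:
    """Fetch a registered parameter set by name, optionally overriding
    fields (including the ``ed_ratio`` shorthand)."""
    try:
        base = PARAMETER_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; known: {sorted(PARAMETER_SETS)}"
        ) from None
    return base.with_(**overrides) if overrides else base
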