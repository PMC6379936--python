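"""Core data types for the hOGG1 excision-kinetics and thermostability pipeline.

Units are fixed throughout the package: time in minutes, concentrations in
nM (on the 20 nM labeled-substrate scale of the excision assay),
temperatures in degrees Celsius at the API surface (Kelvin internally for
thermodynamics), molar ellipticity in degree·cm²·dmol⁻¹, and the van't
Hoff enthalpy in kJ·mol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "InsufficientDataError",
    "AlignmentError",
    "NoTransitionError",
    "PairingError",
    "DegenerateDataError",
    "ConfigurationError",
    "BurstParams",
    "TimeCourse",
    "BurstFit",
    "MeltCurve",
    "MeltFit",
    "VariantSpec",
    "GelLanes",
    "PreincubationCondition",
    "RetentionResult",
]


class DomainError(ValueError):
    """An argument is outside the physically meaningful domain."""


class InsufficientDataError(ValueError):
    """Too few (distinct) observations for the requested fit."""


class AlignmentError(ValueError):
    """Replicate grids do not align within tolerance."""


class NoTransitionError(ValueError):
    """A melting curve shows no interior unfolding transition."""


class PairingError(ValueError):
    """Two results being compared do not form a valid pair."""


class DegenerateDataError(ValueError):
    """No activity metric can be computed from the available data."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (e.g. smoothing window)."""


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the biphasic product-formation model.

    ``P(t) = A0 * (1 - exp(-k1 * t)) + k2 * t``

    Attributes
    ----------
    A0 : burst amplitude, nM. Proportional to actively engaged enzyme.
    k1 : burst-phase (first-turnover) rate constant, min⁻¹.
    k2 : steady-state linear-phase rate, nM·min⁻¹.
    """

    A0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.A0 >= 0):
            raise DomainError(f"burst amplitude A0 must be >= 0, got {self.A0}")
        if not (self.k1 > 0):
            raise DomainError(f"burst rate k1 must be > 0, got {self.k1}")
        if not (self.k2 >= 0):
            raise DomainError(f"linear rate k2 must be >= 0, got {self.k2}")

    def check_amplitude(self, substrate_total: float) -> None:
        """Raise if the burst amplitude exceeds the total substrate."""
        if self.A0 > substrate_total:
            raise DomainError(
                f"A0 = {self.A0} nM exceeds substrate total {substrate_total} nM"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.A0, self.k1, self.k2], dtype=float)


@dataclass
class TimeCourse:
    """Product-formation measurements for one variant under one condition.

    Points from several replicates may be pooled; the ``replicate`` column
    keeps them distinguishable. ``sd`` is populated by replicate averaging.
    """

    variant: str
    condition: str
    substrate_total: float
    time: np.ndarray        # min
    product: np.ndarray     # nM
    replicate: np.ndarray   # replicate labels, one per point
    sd: Optional[np.ndarray] = None  # per-point SD after averaging

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (self.time.shape == self.product.shape == self.replicate.shape):
            raise ValueError("time, product and replicate must have equal length")
        if self.substrate_total <= 0:
            raise DomainError("substrate_total must be positive")
        if np.any(self.time < 0):
            raise DomainError("negative time in time course")
        if np.any(self.product < 0):
            raise DomainError("negative product concentration in time course")
        if np.any(self.product > self.substrate_total + 1e-9):
            raise DomainError(
                "product exceeds substrate total "
                f"({self.product.max():.3g} > {self.substrate_total:.3g} nM)"
            )
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def distinct_times(self) -> np.ndarray:
        return np.unique(self.time)

    @property
    def replicate_ids(self) -> list:
        """Replicate labels in order of first appearance."""
        seen: dict = {}
        for r in self.replicate.tolist():
            seen.setdefault(r, None)
        return list(seen)

    def split_replicates(self) -> list["TimeCourse"]:
        """One single-replicate TimeCourse per replicate label."""
        out = []
        for rid in self.replicate_ids:
            m = self.replicate == rid
            out.append(
                TimeCourse(
                    variant=self.variant,
                    condition=self.condition,
                    substrate_total=self.substrate_total,
                    time=self.time[m],
                    product=self.product[m],
                    replicate=self.replicate[m],
                )
            )
        return out


@dataclass
class BurstFit:
    """Result of fitting the burst model (or its linear reduction) to data.

    For ``model == "linear_only"`` the burst quantities ``A0``/``k1`` (and
    their standard errors) are ``None``: the amplitude of a burst that the
    data do not support is reported absent, not as zero with a spurious
    uncertainty.
    """

    model: str                      # "burst" | "linear_only"
    A0: Optional[float]
    k1: Optional[float]
    k2: float
    se: dict                        # parameter name -> standard error
    cov: np.ndarray                 # covariance of the free parameters
    rss: float
    n_points: int
    substrate_total: float
    variant: str = ""
    condition: str = ""
    converged: bool = True
    message: str = ""
    bootstrap_se: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.model not in ("burst", "linear_only"):
            raise ValueError(f"unknown model {self.model!r}")
        for name, v in self.se.items():
            if v is not None and v < 0:
                raise ValueError(f"negative standard error for {name}")

    @property
    def params(self) -> BurstParams:
        if self.model != "burst":
            raise DegenerateDataError(
                "linear_only fit has no burst parameters"
            )
        return BurstParams(A0=self.A0, k1=self.k1, k2=self.k2)


@dataclass
class MeltCurve:
    """One CD thermal-denaturation trace (222 nm channel) for one replicate."""

    variant: str
    replicate: str
    temperature: np.ndarray  # °C, strictly increasing
    theta222: np.ndarray     # molar ellipticity, degree·cm²·dmol⁻¹

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.theta222 = np.asarray(self.theta222, dtype=float)
        if self.temperature.shape != self.theta222.shape:
            raise ValueError("temperature and theta222 must have equal length")
        if self.temperature.size and (
            self.temperature.min() < 0 or self.temperature.max() > 100
        ):
            raise DomainError("temperatures must lie within [0, 100] °C")
        if np.any(np.diff(self.temperature) <= 0):
            raise DomainError("temperatures must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.temperature.size)


@dataclass
class MeltFit:
    """Two-state unfolding description fitted to a melting curve."""

    tm: float                        # °C
    dh_vh: float                     # van't Hoff enthalpy, kJ·mol⁻¹
    native_baseline: tuple           # (intercept, slope) of θ_N(T)
    denatured_baseline: tuple        # (intercept, slope) of θ_D(T)
    method: str                      # "two_state_fit" | "derivative"
    se_tm: Optional[float]           # °C
    rss: float = float("nan")
    n_points: int = 0
    variant: str = ""
    tm_derivative: Optional[float] = None  # cross-check estimate, °C
    message: str = ""

    def __post_init__(self) -> None:
        if self.method == "two_state_fit" and not (self.dh_vh > 0):
            raise DomainError("a cooperative transition requires dH_vH > 0")


@dataclass(frozen=True)
class VariantSpec:
    """Ground-truth generative parameters for one hOGG1 variant.

    The excision kinetics and the melting midpoint come from published
    measurements; the irreversible-denaturation kinetics (``k_den_ref``,
    ``alpha``) and the DNA-protection factor are the synthetic generator's
    own model of activity loss during pre-incubation.
    """

    name: str
    burst: BurstParams
    tm: float                 # °C
    dh_vh: float = 200.0      # kJ·mol⁻¹
    k_den_ref: float = 0.025  # min⁻¹, denaturation rate at T = Tm
    alpha: float = 0.7        # °C⁻¹, temperature sensitivity of k_den
    dna_protection: float = 0.05  # multiplies k_den when competitor DNA bound

    def __post_init__(self) -> None:
        if self.k_den_ref < 0 or self.alpha < 0:
            raise DomainError("denaturation rates must be >= 0")
        if not (0 <= self.dna_protection <= 1):
            raise DomainError("dna_protection must lie in [0, 1]")
        if not (0 < self.tm < 100):
            raise DomainError("Tm must lie in (0, 100) °C")
        if self.dh_vh <= 0:
            raise DomainError("dh_vh must be positive")


@dataclass
class GelLanes:
    """Abstract densitometry of a quench time-course gel.

    Each lane carries the intact 20-mer substrate band and the 9-mer
    cleavage-product band of the excision assay.
    """

    time: np.ndarray         # min, one per lane
    i_substrate: np.ndarray  # intensity of the 20-mer band
    i_product: np.ndarray    # intensity of the 9-mer band
    variant: str = ""
    condition: str = ""
    substrate_total: float = 20.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.i_substrate = np.asarray(self.i_substrate, dtype=float)
        self.i_product = np.asarray(self.i_product, dtype=float)
        if not (self.time.shape == self.i_substrate.shape == self.i_product.shape):
            raise ValueError("per-lane arrays must have equal length")
        if np.any(self.i_substrate < 0) or np.any(self.i_product < 0):
            raise DomainError("band intensities must be >= 0")


@dataclass(frozen=True)
class PreincubationCondition:
    """Thermal-challenge condition applied before the excision assay."""

    temperature: float               # °C (study values: 4 or 37)
    duration: float = 90.0           # min
    competitor_dna: bool = False
    competitor_stoichiometry: float = 0.0  # ratio to enzyme; 1.0 in the study

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise DomainError("duration must be >= 0")
        if self.competitor_stoichiometry < 0:
            raise DomainError("stoichiometry must be >= 0")
        if self.competitor_stoichiometry > 0 and not self.competitor_dna:
            raise DomainError(
                "competitor stoichiometry > 0 requires the competitor flag"
            )

    @property
    def label(self) -> str:
        base = f"pre{self.temperature:g}"
        return base + "+DNA" if self.competitor_dna else base


def parse_condition_label(label: str) -> PreincubationCondition:
    """Parse a condition label such as ``"pre37+DNA"`` or ``"pre4"``."""
    s = label.strip()
    if not s.startswith("pre"):
        raise ValueError(f"not a pre-incubation condition label: {label!r}")
    body = s[3:]
    dna = body.endswith("+DNA")
    if dna:
        body = body[: -len("+DNA")]
    try:
        temp = float(body)
    except ValueError as exc:
        raise ValueError(f"cannot parse temperature from {label!r}") from exc
    return PreincubationCondition(
        temperature=temp,
        competitor_dna=dna,
        competitor_stoichiometry=1.0 if dna else 0.0,
    )


@dataclass
class RetentionResult:
    """Activity retained after thermal challenge, relative to the 4 °C control."""

    variant: str
    retention: float
    ci_low: float
    ci_high: float
    metric: str                      # "burst_amplitude" | "fixed_time_product"
    condition_pair: tuple            # (challenged label, control label)
    n_replicates: tuple = (0, 0)     # (challenged, control)
    flagged: bool = False            # retention > 1.1 (or metric fallback)
    draws: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.retention <= self.ci_high + 1e-12):
            raise ValueError("retention must lie within its confidence interval")
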