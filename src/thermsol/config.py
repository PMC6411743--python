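"""Analysis and simulation configuration objects.

Two small dataclasses carry every tunable of the package: :class:`AnalysisConfig`
for the statistical pipelines and :class:`SimConfig` for the synthetic-data
generators.  Both can be round-tripped through YAML so that command-line runs
are fully reproducible from a single config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Standard temperature gradient (degC) of a single-dose melting-range experiment.
TR_TEMPERATURES = (37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3)

#: Temperature gradient (degC) of the dose x temperature (2D) design.
TPP2D_TEMPERATURES = (42.0, 44.1, 46.2, 48.1, 50.4, 51.9, 54.0, 56.1, 58.2, 60.1)

#: Ligand doses (mM, 0 = vehicle) of the standard 2D design (Na-ATP grid).
TPP2D_CONCENTRATIONS = (0.0, 0.005, 0.05, 0.5, 2.0)

#: Ligand doses (mM, 0 = vehicle) of the solubility (SPP) design.
SPP_CONCENTRATIONS = (0.0, 0.1, 0.5, 1.0, 2.0, 4.0, 5.0, 8.0, 10.0)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the 2D-TPP / SPP / melting pipelines.

    Parameters
    ----------
    h : float
        Fold-change gate applied to window extrema and hit calling; a window or
        profile only counts as responsive when its most extreme fold change is
        above ``h`` or below ``1/h``.  Must exceed 1.
    fdr_cutoff : float
        Permutation FDR level at which hits are called.
    n_permutations : int
        Number of stratified permutations (``B``) for FDR estimation.
    min_points_per_fit : int
        Minimum number of (dose, fold change) points required before a
        dose-response model is fitted at all.
    seed : int
        Master seed for the permutation RNG.
    comelt_cutoff : float
        Profile-distance cutoff below which two melting profiles are called
        "in proximity" (co-melting).
    insoluble_ratio : float
        SDS/NP40 vehicle ratio at and above which a protein is classified as
        part of the insoluble proteome.
    include_vehicle_point : bool
        Whether the vehicle (dose 0, fold change 1) enters the dose-response
        fit.
    vehicle_mode : str
        How the vehicle point is placed on the dose axis: ``"asymptote"``
        (default) evaluates the model at its no-ligand limit, which is
        unbiased at every affinity; ``"pseudo_dose"`` places it two decades
        below the lowest tested dose (common practice with off-the-shelf
        fitters, but it biases the inflection estimate once the EC50
        approaches the bottom of the dose range).
    allow_negative_log_terms : bool
        If True, the combined score sums ln(F) terms even when negative;
        default floors each term at zero so windows with F < 1 carry no
        evidence either way.
    fit_on_log : bool
        If True the solubility dose-response models are fitted on log2 fold
        changes instead of raw ratios.
    window_size : int
        Number of consecutive temperatures pooled per sliding window.
    comelt_distance_mode : str
        ``"mean_sq"`` (average squared deviation per temperature, default) or
        ``"rss"`` (root-sum-square) for the melting-profile distance.
    """

    h: float = 1.5
    fdr_cutoff: float = 0.01
    n_permutations: int = 100
    min_points_per_fit: int = 5
    seed: int = 0
    comelt_cutoff: float = 0.02
    insoluble_ratio: float = 1.5
    include_vehicle_point: bool = True
    vehicle_mode: str = "asymptote"
    allow_negative_log_terms: bool = False
    fit_on_log: bool = False
    window_size: int = 2
    comelt_distance_mode: str = "mean_sq"
    melting_r2_min: float = 0.8
    melting_plateau_max: float = 0.3

    def __post_init__(self) -> None:
        if not self.h > 1:
            raise ValueError(f"fold-change gate h must exceed 1, got {self.h}")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError(f"fdr_cutoff must lie in (0, 1), got {self.fdr_cutoff}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.comelt_distance_mode not in ("mean_sq", "rss"):
            raise ValueError(f"unknown comelt_distance_mode {self.comelt_distance_mode!r}")
        if self.vehicle_mode not in ("asymptote", "pseudo_dose"):
            raise ValueError(f"unknown vehicle_mode {self.vehicle_mode!r}")


@dataclass
class SimConfig:
    """Ground-truth generator settings for one synthetic experiment.

    ``fractions`` maps effect classes to proportions of the simulated proteome
    and must sum to 1.  Valid classes depend on the experiment kind:
    ``null``/``stabilized``/``destabilized`` for the thermal designs and
    ``null``/``solubilized``/``desolubilized`` for the solubility design.

    The defaults emulate the published experimental designs: a TMT10-based
    dose x temperature grid (five doses, ten temperatures, plexes spanning two
    neighboring temperatures), an SPP plex of one NP40 vehicle + eight NP40
    doses + one SDS vehicle, and a ten-temperature melting-range layout.
    Multiplicative lognormal noise with coefficient of variation ``noise_cv``
    is applied to every intensity.
    """

    kind: str = "tpp2d"
    n_proteins: int = 200
    fractions: dict = field(default_factory=lambda: {"null": 1.0})
    pec50_range: tuple = (3.5, 6.5)
    noise_cv: float = 0.1
    temperatures: tuple = TPP2D_TEMPERATURES
    concentrations_mM: tuple = TPP2D_CONCENTRATIONS
    n_replicates: int = 3
    max_effect: float = 3.0
    # melting-curve truth
    tm_range: tuple = (46.0, 56.0)
    tm_shift_range: tuple = (2.0, 6.0)
    plateau_range: tuple = (0.0, 0.15)
    slope_scale: float = 550.0
    # solubility truth
    insoluble_fraction_range: tuple = (0.4, 0.8)
    soluble_background_fraction: float = 0.7
    release_range: tuple = (0.6, 1.0)
    # protein complexes
    n_complexes: int = 0
    complex_size: int = 5
    complex_jitter: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"effect-class fractions must sum to 1, got {total}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        temps = tuple(self.temperatures)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be positive")

    @classmethod
    def tpp2d(cls, **kw) -> "SimConfig":
        """2D design: dose grid x temperature gradient, TMT10 plexes over
        two neighboring temperatures."""
        kw.setdefault("kind", "tpp2d")
        kw.setdefault("temperatures", TPP2D_TEMPERATURES)
        kw.setdefault("concentrations_mM", TPP2D_CONCENTRATIONS)
        kw.setdefault("fractions", {"null": 0.85, "stabilized": 0.10, "destabilized": 0.05})
        kw.setdefault("pec50_range", (3.5, 6.5))
        return cls(**kw)

    @classmethod
    def spp(cls, **kw) -> "SimConfig":
        """Solubility design: NP40 vehicle + eight NP40 doses + SDS vehicle.

        The default half-maximal solubilization concentrations lie inside the
        tested dose window (0.1-10 mM), where they are identifiable.
        """
        kw.setdefault("kind", "spp")
        kw.setdefault("temperatures", (37.0,))
        kw.setdefault("concentrations_mM", SPP_CONCENTRATIONS)
        kw.setdefault("fractions", {"null": 0.80, "solubilized": 0.15, "desolubilized": 0.05})
        kw.setdefault("pec50_range", (2.5, 4.5))
        return cls(**kw)

    @classmethod
    def tpp_tr(cls, **kw) -> "SimConfig":
        """Melting-range design: ten temperatures, vehicle vs treated."""
        kw.setdefault("kind", "tpp_tr")
        kw.setdefault("temperatures", TR_TEMPERATURES)
        kw.setdefault("concentrations_mM", (0.0,))
        kw.setdefault("n_replicates", 2)
        kw.setdefault("fractions", {"null": 0.85, "stabilized": 0.10, "destabilized": 0.05})
        return cls(**kw)


def read_config_overrides(path: str | Path, cls=AnalysisConfig) -> dict:
    """Read a YAML/JSON config file into validated keyword overrides."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    if isinstance(payload.get("fractions"), dict):
        # YAML parses a bare `null:` key as None; it means the null class
        payload["fractions"] = {
            ("null" if k is None else str(k)): v
            for k, v in payload["fractions"].items()
        }
    for f in dataclasses.fields(cls):
        if f.name in payload and isinstance(payload[f.name], list):
            payload[f.name] = tuple(payload[f.name])
    return payload


def load_config(path: str | Path, cls=AnalysisConfig):
    """Read an :class:`AnalysisConfig` or :class:`SimConfig` from YAML/JSON."""
    return cls(**read_config_overrides(path, cls))


def save_config(cfg, path: str | Path) -> None:
    """Write a config dataclass to YAML."""
    payload = dataclasses.asdict(cfg)
    for key, value in payload.items():
        if isinstance(value, tuple):
            payload[key] = list(value)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
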