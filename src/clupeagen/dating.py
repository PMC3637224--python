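"""Molecular-clock arithmetic for invasion dating and TMRCA estimates.

All rates are stored internally as per-lineage, per-site, per-year
substitution rates; percent-per-My divergence rates and per-gene mutation
units are derived presentation-layer conversions. Keeping one canonical
unit avoids the factor-of-2 (lineage vs divergence) and factor-of-L
(site vs gene) errors that plague clock arithmetic.

Estimators implemented:

* direct-count dating — under a star coalescence (sudden founder
  expansion) with per-gene per-year mutation rate mu and no drift or
  migration since founding, a sample of N individuals is expected to carry
  n = t * mu * N post-founding mutations; inverting gives the (minimum)
  age t = n / (mu * N).
* per-gene mutation-unit conversion — coalescent samplers report split
  times in expected mutations per gene copy; dividing by mu (per gene per
  year) converts to years.
* TMRCA from a basal divergence — a between-lineage divergence d (%)
  divided by the divergence rate (%/My) gives the coalescence age in My.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RateCalibration:
    """Clock calibration: per-lineage site rate, gene length, generation time.

    ``per_lineage_site_rate`` is in substitutions/site/year (e.g. 0.75e-8
    for a 0.75%-per-My per-lineage rate); ``gene_length`` in bp;
    ``generation_years`` in years.
    """

    per_lineage_site_rate: float
    gene_length: int
    generation_years: float = 4.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.per_lineage_site_rate <= 0:
            raise ValueError("rate must be positive")
        if self.gene_length <= 0:
            raise ValueError("gene length must be positive")
        if self.generation_years <= 0:
            raise ValueError("generation interval must be positive")

    @property
    def divergence_rate_percent_per_my(self) -> float:
        """Pairwise divergence rate in %/My (2x the per-lineage rate)."""
        return 2.0 * self.per_lineage_site_rate * 1e8

    @property
    def per_lineage_percent_per_my(self) -> float:
        return self.per_lineage_site_rate * 1e8

    @property
    def mu_gene_per_year(self) -> float:
        """Per-gene per-lineage mutation rate, /year."""
        return self.per_lineage_site_rate * self.gene_length

    @property
    def mu_site_per_generation(self) -> float:
        return self.per_lineage_site_rate * self.generation_years

    @classmethod
    def from_percent_per_my(
        cls,
        per_lineage_percent_per_my: float,
        gene_length: int,
        generation_years: float = 4.0,
        name: str = "",
    ) -> "RateCalibration":
        return cls(
            per_lineage_site_rate=per_lineage_percent_per_my * 1e-8,
            gene_length=gene_length,
            generation_years=generation_years,
            name=name,
        )


def cytb_calibration() -> RateCalibration:
    """Operational cytochrome-b calibration: 0.75%/My per lineage, 1131 bp."""
    return RateCalibration.from_percent_per_my(0.75, 1131, 4.0, name="cyt-b")


def cr_calibration(rate_ratio: float = 3.6, length: int = 481) -> RateCalibration:
    """Control-region calibration derived from cyt-b by a rate ratio."""
    return RateCalibration.from_percent_per_my(0.75 * rate_ratio, length, 4.0, name="CR")


@dataclass(frozen=True)
class IMParameterSet:
    """Isolation-with-migration posterior point estimates (stored/converted only).

    ``t_gene_units`` is the split time in expected mutations per gene copy;
    ``split_fraction`` is the founding fraction s of the ancestral
    population that seeded the smaller descendant; ``m1``/``m2`` are
    migration/mutation-rate ratios.
    """

    theta_ancestral: float
    split_fraction: float
    m1: float
    m2: float
    t_gene_units: float
    t_hpd: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0, 1)")
        if self.t_gene_units < 0:
            raise ValueError("split time must be >= 0")

    def split_years(self, calib: RateCalibration) -> float:
        return gene_units_to_years(self.t_gene_units, calib)


@dataclass(frozen=True)
class DirectCountResult:
    n_mutations: int
    n_individuals: int
    t_years: float
    calibration: RateCalibration

    @property
    def t_ky(self) -> float:
        return self.t_years / 1000.0


def direct_count_age(
    n_mutations: int, n_individuals: int, calib: RateCalibration
) -> DirectCountResult:
    """Star-coalescence direct-count age: t = n / (mu_gene * N) years.

    A minimum estimate: coalescence among sampled lineages after founding
    only reduces the observable mutation count.
    """
    if n_individuals < 1:
        raise ValueError("need at least one sampled individual")
    if n_mutations < 0:
        raise ValueError("mutation count must be >= 0")
    t = n_mutations / (calib.mu_gene_per_year * n_individuals)
    return DirectCountResult(
        n_mutations=n_mutations,
        n_individuals=n_individuals,
        t_years=t,
        calibration=calib,
    )


def expected_new_mutations(
    t_years: float, n_individuals: int, calib: RateCalibration
) -> float:
    """Forward direction: expected post-founding mutations n = t * mu_gene * N."""
    if t_years < 0:
        raise ValueError("age must be >= 0")
    return t_years * calib.mu_gene_per_year * n_individuals


def gene_units_to_years(t_gene_units: float, calib: RateCalibration) -> float:
    """Convert a per-gene mutation-unit time to years: t / (rate * L)."""
    if t_gene_units < 0:
        raise ValueError("time must be >= 0")
    return t_gene_units / calib.mu_gene_per_year


def divergence_to_tmrca(d_percent: float, calib: RateCalibration) -> float:
    """TMRCA in My from a pairwise divergence in % and the divergence rate."""
    if d_percent < 0:
        raise ValueError("divergence must be >= 0")
    return d_percent / calib.divergence_rate_percent_per_my


def partition_rate_ratio(d_partition_1: float, d_partition_2: float) -> float:
    """Ratio of modeled divergences at a shared calibration anchor.

    Used to derive a control-region rate from a fixed coding-gene rate
    (e.g. interspecies divergences of 16.9% vs 4.7% imply a 3.6x faster
    control region).
    """
    if d_partition_2 <= 0:
        raise ValueError("denominator divergence must be positive")
    return d_partition_1 / d_partition_2


def satellite_fraction(n_mutations: int, n_individuals: int) -> float:
    """Inferred post-bottleneck mutations as a percentage of the sample."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    return 100.0 * n_mutations / n_individuals


def format_ky(t_years: float) -> str:
    """Round to the nearest thousand years, e.g. 20244 -> '20 ky'."""
    return f"{round(t_years / 1000.0):.0f} ky"


def format_my(t_my: float) -> str:
    """One-decimal My formatting, e.g. 3.113 -> '3.1 My'."""
    return f"{t_my:.1f} My"
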