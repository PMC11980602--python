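"""Simulation configuration.

All tunables of the synthetic activated-sludge community live in
:class:`SimConfig`.  Defaults describe a 6-year monthly time series: a
temporally stable bacterial community with a persistent core, a
high-turnover seasonal phage community, defense-system (DS) abundance that
trails total phage abundance by ``lag_months``, and CRISPR spacer
repertoires with fast memoryless loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ConfigError

#: DS types used by default; the abundant types observed in activated sludge
#: (restriction-modification, CRISPR-Cas, SoFIC, AbiE ...) plus other
#: widespread systems.
DEFAULT_DS_TYPES = [
    "RM",
    "CRISPR-Cas",
    "SoFIC",
    "AbiE",
    "Gabija",
    "Thoeris",
    "Wadjet",
    "Septu",
    "Hachiman",
    "Lamassu",
    "Zorya",
    "MazEF",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic community generator.

    Attributes
    ----------
    n_months:
        Length of the monthly time series (72 = 6 years).
    n_bacteria:
        Number of bacterial species.
    n_phages:
        Size of the initial vOTU pool; new vOTUs also arrive over time.
    ds_types:
        Defense-system type names to simulate.
    lag_months:
        Planted lag (months) by which DS abundance trails phage abundance.
    coupling_beta:
        Strength of the DS response to total phage abundance (per unit
        phage abundance; ≥ 0, 0 decouples the two).
    noise_sd:
        SD of the log-multiplicative noise on bacterial abundances and of
        the additive Gaussian noise on DS series.
    season_amp:
        Amplitude of the 12-month sinusoid modulating phage abundances.
    phage_arrival_rate:
        Mean number of newly arriving vOTUs per month (Poisson).
    phage_decay_rate:
        Per-month geometric decay fraction of a vOTU past its peak
        (1.0 = complete collapse in one step).
    spacer_acq_slope:
        Spacer acquisition probability per unit vOTU abundance
        (p = min(1, slope * abundance) per vOTU per month).
    spacer_loss_prob:
        Per-month probability that an existing spacer is lost. 0.9 gives
        the rapid repertoire turnover seen in activated sludge.
    spacer_background_rate:
        Mean number of non-targeting background spacers acquired per month.
    spacer_mismatch_prob:
        Probability that an acquired spacer carries exactly one
        substitution relative to its protospacer.
    votu_seq_len:
        Length (bp) of each synthetic vOTU sequence.
    n_mag_clusters, mag_cluster_size, mag_core_ds, mag_accessory_pool,
    mag_accessory_draw, mag_frac_no_ds:
        Shape of the MAG panel: number of ANI≥95% clusters, (min, max)
        members per cluster, size of the shared core DS set, size of the
        cluster-specific accessory DS pool, (min, max) accessory DSs drawn
        per MAG, and the fraction of MAGs carrying no DS at all.
    seed:
        Master seed; every component derives its own stream from it.
    """

    n_months: int = 72
    n_bacteria: int = 100
    n_phages: int = 40
    ds_types: list[str] = field(default_factory=lambda: list(DEFAULT_DS_TYPES))
    lag_months: int = 2
    coupling_beta: float = 1.0
    noise_sd: float = 0.05
    season_amp: float = 0.3
    phage_arrival_rate: float = 1.0
    phage_decay_rate: float = 0.25
    spacer_acq_slope: float = 0.15
    spacer_loss_prob: float = 0.9
    spacer_background_rate: float = 5.0
    spacer_mismatch_prob: float = 0.0
    votu_seq_len: int = 2000
    n_mag_clusters: int = 8
    mag_cluster_size: tuple[int, int] = (3, 8)
    mag_core_ds: int = 2
    mag_accessory_pool: int = 6
    mag_accessory_draw: tuple[int, int] = (1, 4)
    mag_frac_no_ds: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_months < 2:
            raise ConfigError("n_months: must be >= 2")
        if self.n_bacteria < 1:
            raise ConfigError("n_bacteria: must be >= 1")
        if self.n_phages < 0:
            raise ConfigError("n_phages: must be >= 0")
        if not self.ds_types:
            raise ConfigError("ds_types: must be non-empty")
        if self.lag_months < 0:
            raise ConfigError("lag_months: must be >= 0")
        if self.n_months < 2 * self.lag_months + 12:
            raise ConfigError(
                "n_months: must be >= 2*lag_months + 12 "
                f"(got {self.n_months} with lag_months={self.lag_months})"
            )
        if self.coupling_beta < 0:
            raise ConfigError("coupling_beta: must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        if self.season_amp < 0:
            raise ConfigError("season_amp: must be >= 0")
        if self.phage_arrival_rate < 0:
            raise ConfigError("phage_arrival_rate: must be >= 0")
        if not (0 < self.phage_decay_rate <= 1):
            raise ConfigError("phage_decay_rate: must be in (0, 1]")
        if self.spacer_acq_slope < 0:
            raise ConfigError("spacer_acq_slope: must be >= 0")
        if not (0 <= self.spacer_loss_prob <= 1):
            raise ConfigError("spacer_loss_prob: must be in [0, 1]")
        if self.spacer_background_rate < 0:
            raise ConfigError("spacer_background_rate: must be >= 0")
        if not (0 <= self.spacer_mismatch_prob <= 1):
            raise ConfigError("spacer_mismatch_prob: must be in [0, 1]")
        if self.votu_seq_len < 60:
            raise ConfigError("votu_seq_len: must be >= 60")
        if not (0 <= self.mag_frac_no_ds <= 1):
            raise ConfigError("mag_frac_no_ds: must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)
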