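"""Pipeline configuration.

Every analysis threshold used by the census is a config key whose default
is the value adopted throughout the study design this package models
(tau >= 0.9 for tissue restriction, fold-change > 2 with BH p < 0.05 for
Aire regulation, FDR < 0.05 with |dPSI| > 0.2 for differential splicing,
npIDR <= 0.1 for reproducible detection, and so on). Configurations are
plain dataclasses loadable from a two-section YAML file::

    simulation:
      n_genes: 300
    analysis:
      tau_threshold: 0.9
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "AnalysisConfig", "load_config", "dump_config"]

# 21 peripheral tissues, mirroring the breadth of the mouse ENCODE panel the
# census is designed around. "cerebellum" doubles as the neural tissue in
# which planted microexons are included.
DEFAULT_TISSUES = (
    "adrenal", "bladder", "cerebellum", "colon", "cortex", "duodenum",
    "heart", "kidney", "liver", "lung", "mammary", "muscle", "olfactory",
    "ovary", "pancreas", "placenta", "smallintestine", "spleen", "stomach",
    "testis", "thyroid",
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator (planted ground truth).

    The defaults emulate the study design the analyses target: a 21-tissue
    peripheral panel plus immature / mature (Aire-positive) / Aire-knockout
    TEC-like samples with two replicates each, roughly 40% tissue-restricted
    genes of which 40% are Aire-dependent, a TEC-like sample that expresses
    tissue-restricted genes at a few percent of their home-tissue level and
    through only half of their isoforms, planted differential-splicing
    events of |dPSI| = 0.4, and a five-fold positional enrichment of the
    RBFOX recognition motif next to splicing-enhanced exons.
    """

    n_tissues: int = 21
    n_genes: int = 1000
    isoforms_per_gene: tuple[int, int] = (2, 6)
    frac_tra: float = 0.4
    frac_aire: float = 0.4
    tec_isoform_fraction: float = 0.5
    planted_delta_psi: float = 0.4
    motif_enrichment_rate: float = 5.0
    noise: float = 0.1          # negative-binomial dispersion on counts
    seed: int = 0

    # gene architecture
    n_exons: tuple[int, int] = (4, 10)
    n_exons_tra: tuple[int, int] = (25, 40)   # TRA genes are junction-rich
    isoforms_per_tra_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (700, 1200)
    microexon_fraction: float = 0.1           # of cassette exons, length <= 30
    microexon_length: tuple[int, int] = (9, 30)
    biased_cassette_fraction: float = 0.3     # non-TRA cassettes with tissue-biased usage

    # expression model
    mean_log_tpm: float = 2.3                 # ln scale of gene abundance
    sd_log_tpm: float = 1.6
    non_tra_tissue_presence: float = 0.9      # per-tissue expression prob, non-TRA
    tpm_lognorm_sigma: float = 0.2            # per-sample multiplicative noise
    tec_expression_fraction: float = 0.05     # TRA level in TEC vs home tissue
    immature_tra_fraction: float = 0.25       # immature vs mature TRA level
    aire_ko_fold: float = 4.0                 # Aire-TRA down-regulation in KO

    # count scales
    count_depth: float = 30.0                 # expected counts per TPM
    junction_coverage: float = 50.0           # expected junction reads per 100 TPM

    # event-count generator
    event_coverage: int = 100                 # reads per event per replicate

    # replicate-pool detection model (logistic in log10 TPM)
    detect_dropout: bool = True
    detect_midpoint_log10tpm: float = 0.3
    detect_slope: float = 3.0
    detect_floor_tpm: float = 0.0             # detection prob 0 below this TPM

    # motif planting
    motif: str = "WGCAUGM"
    motif_background_per_kb: float = 1.0

    tissues: tuple[str, ...] = DEFAULT_TISSUES

    def __post_init__(self) -> None:
        for name in ("frac_tra", "frac_aire", "tec_isoform_fraction",
                     "planted_delta_psi", "microexon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3")
        if self.n_tissues > len(self.tissues):
            raise ValueError("n_tissues exceeds the named tissue list")
        if self.noise < 0:
            raise ValueError("dispersion must be non-negative")

    @property
    def tissue_names(self) -> list[str]:
        return list(self.tissues[: self.n_tissues])


@dataclass
class AnalysisConfig:
    """Thresholds and options of the analysis stages."""

    # tissue specificity
    tau_threshold: float = 0.9
    sf_tau_threshold: float = 0.5
    tau_log_transform: bool = True
    # Aire regulation
    aire_fc_threshold: float = 2.0
    aire_alpha: float = 0.05
    # reproducibility filter
    npidr_threshold: float = 0.1
    npidr_bins: int = 20
    # detection census
    detection_threshold: float = 0.0
    detection_grid: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0)
    # junction census
    junction_min_reads: int = 1
    junction_fc_threshold: float = 2.0
    junction_alpha: float = 0.05
    no_replicate_dispersion: float = 0.1
    # differential splicing
    event_fdr: float = 0.05
    event_delta_psi: float = 0.2
    psi_min_tpm: float = 1.0
    psi_min_reads: int = 10
    # exon-pattern / microexon analyses
    exon_min_length: int = 50
    microexon_max_length: int = 30
    # transcript usage
    usage_fc_threshold: float = 2.0
    usage_alpha: float = 0.05
    # motif enrichment
    motif: str = "WGCAUGM"
    intron_window: int = 250
    exon_window: int = 50
    smooth_width: int = 31
    n_permutations: int = 1000
    motif_fdr: float = 0.05


def _coerce(cls, raw: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path: str | Path | None = None) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load (simulation, analysis) configuration from a YAML file.

    Missing keys fall back to the defaults; unknown keys raise ``KeyError``.
    """
    if path is None:
        return SimulationConfig(), AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    extra = set(raw) - {"simulation", "analysis"}
    if extra:
        raise KeyError(f"unknown config sections: {sorted(extra)}")
    sim = _coerce(SimulationConfig, raw.get("simulation", {}) or {})
    ana = _coerce(AnalysisConfig, raw.get("analysis", {}) or {})
    return sim, ana


def dump_config(sim: SimulationConfig, ana: AnalysisConfig) -> str:
    """Serialize both sections back to YAML (deterministic key order)."""
    return yaml.safe_dump(
        {"simulation": asdict(sim), "analysis": asdict(ana)}, sort_keys=True
    )
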