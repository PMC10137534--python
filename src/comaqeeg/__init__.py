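"""Quantitative EEG band-power analysis for deep-coma consciousness levels.

A reusable pipeline for discriminating Glasgow Coma Scale (GCS) levels 3-8
from four-channel bipolar EEG recorded under a staged stimulus protocol
(rest / nurse interaction / rest / family interaction / rest, 35 min total):
band decomposition into delta/theta/alpha/beta, Welch power-spectral-density
feature extraction (10 features x 4 bands x 4 channels = 160 per instance),
nonparametric group screening (Kruskal-Wallis + Dunn-Bonferroni), SMOTE
class balancing, and multiclass classification with one-vs-rest,
imbalance-aware metrics.  A synthetic-cohort generator with controllable
GCS-dependent spectral structure makes every stage testable end to end.
"""

from .bands import BandDefinition, CANONICAL_BANDS, CHANNEL_LABELS
from .recording import Recording, Stage, StageSchedule, DEFAULT_SCHEDULE
from .segmentation import Segment, build_segments
from .features import (
    WelchConfig,
    PsdEstimate,
    welch_psd,
    parseval_energy,
    extract_feature_vector,
    FEATURE_NAMES,
    feature_column_names,
)
from .synthetic import (
    GcsBandProfile,
    SyntheticCohortConfig,
    default_profiles,
    null_profiles,
    generate_band_limited_noise,
    generate_patient_recording,
    generate_cohort,
)
from .balancing import SmoteConfig, smote_oversample, balance_dataset, plan_arithmetic
from .evaluation import (
    ModelSpec,
    one_vs_rest_counts,
    compute_metrics,
    run_kfold_cv,
    run_leave_one_patient_out,
    roc_auc_ovr,
)

__version__ = "0.1.0"

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "CHANNEL_LABELS",
    "Recording",
    "Stage",
    "StageSchedule",
    "DEFAULT_SCHEDULE",
    "Segment",
    "build_segments",
    "WelchConfig",
    "PsdEstimate",
    "welch_psd",
    "parseval_energy",
    "extract_feature_vector",
    "FEATURE_NAMES",
    "feature_column_names",
    "GcsBandProfile",
    "SyntheticCohortConfig",
    "default_profiles",
    "null_profiles",
    "generate_band_limited_noise",
    "generate_patient_recording",
    "generate_cohort",
    "SmoteConfig",
    "smote_oversample",
    "balance_dataset",
    "plan_arithmetic",
    "ModelSpec",
    "one_vs_rest_counts",
    "compute_metrics",
    "run_kfold_cv",
    "run_leave_one_patient_out",
    "roc_auc_ovr",
]
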