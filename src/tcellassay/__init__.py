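"""tcellassay: analysis of in vitro T cell:PBMC immunogenicity assays.

From well-level proliferation (cpm) and IL-2 ELISpot (spots/well)
measurements to stimulation indices, dual-criterion responder calls,
Poisson limiting-dilution precursor-frequency estimates, cohort
immunogenicity summaries, and HLA-DRB1 representativeness checks —
plus a synthetic-cohort generator with known ground truth.
"""

from importlib import resources

from .assay_model import (
    BASELINE,
    MISSING,
    OTHER,
    DEFAULT_CELLS_PER_WELL,
    DEFAULT_REPLICATES,
    AlleleFrequencyTable,
    AssayWell,
    CohortValidationError,
    HLADataError,
    HLAGenotype,
    ReadoutKind,
    Thresholds,
    ValidationReport,
    WellDataError,
    frame_to_wells,
    read_allele_frequencies,
    read_hla_table,
    read_wells,
    validate_cohort,
    wells_to_frame,
    write_wells,
)
from .synthetic_cohort import (
    CompoundSpec,
    GroundTruth,
    SimulationConfig,
    attach_hla,
    boundary_preset,
    calibration_preset,
    null_config,
    sample_precursors,
    simulate_cohort,
    simulate_elispot_well,
    simulate_proliferation_well,
)
from .response_stats import (
    DonorCompoundCall,
    ReadoutSummary,
    calls_to_frame,
    classify_cohort,
    classify_donor,
    readout_call,
    responder_frequency,
    stimulation_index,
    two_tailed_unpaired_t,
)
from .precursor_frequency import (
    CohortFrequencySummary,
    FrequencyEstimate,
    cohort_frequency_summary,
    donor_frequencies,
    estimate_frequency,
    frequency_likelihood_ci,
    frequency_mle_oracle,
    pooled_donor_frequency,
    score_wells,
)
from .cohort_report import (
    CompoundSummary,
    HLAFrequencyComparison,
    build_report,
    hla_allele_frequencies,
    immunogenicity_plot_table,
    magnitude_table,
    population_correlation,
)

__version__ = "0.1.0"


def cohort_hla_path():
    """Path to the bundled 26-donor HLA typing table (CSV)."""
    return resources.files("tcellassay.data") / "cohort_hla_genotypes.csv"


def synthetic_reference_path():
    """Path to the bundled synthetic DRB1 reference allele-frequency table.

    A stand-in for tests and examples; not an estimate of any real
    population's allele frequencies.
    """
    return resources.files("tcellassay.data") / "synthetic_reference_allele_freqs.csv"
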