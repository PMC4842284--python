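"""midflux: non-targeted mass-isotopolome analysis.

QC filtering of fragment MIDs, ranking of putative flux changes by
mass-isotopomer abundance variation, alignment-based MID similarity networks,
convolution deconvolution of moiety MIDs, and an exact label-propagation
simulator for ground-truth generation.
"""

from importlib import resources

from .core import (
    MID,
    CompoundRecord,
    DataError,
    FragmentMeasurement,
    LabelingDataset,
    SchemaError,
    SimilarityNetwork,
    mean_mid,
    normalize_mid,
    read_mid_table,
    write_mid_table,
)
from .isotopes import (
    DEFAULT_ISOTOPE_TABLE,
    ElementalFormula,
    IsotopeTable,
    convolve_mids,
    correct_natural_abundance,
    natural_abundance_envelope,
)
from .qc import QcThresholds, filter_dataset, fragment_passes_qc, strip_trailing_noise
from .variation import heaviest_common_fragment, rank_by_variation, variation_score
from .similarity import (
    align_mid_vectors,
    build_similarity_network,
    mid_distance,
    nearest_neighbors,
    pairwise_distances,
)
from .deconvolution import (
    build_convolution_system,
    deconvolve_moiety,
    solve_complementary_mid,
)
from .simulate import (
    NetworkModel,
    compile_model,
    fragment_mid,
    generate_dataset,
    load_model,
    simulate_labeling,
)

__version__ = "0.1.0"


def toy_model_path():
    """Path to the packaged toy glycolysis/TCA-like network description."""
    return resources.files("midflux") / "data" / "toy_network.yaml"


def load_toy_model() -> NetworkModel:
    return load_model(toy_model_path())
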