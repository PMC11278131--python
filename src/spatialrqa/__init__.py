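"""spatialrqa: spatial heterogeneous recurrence quantification of image patches.

Feature extraction (Haar DWT → Hilbert-curve flattening → delay embedding →
quadtree symbolization → per-cell recurrence statistics), cohort-comparison
statistics (logistic LASSO selection, Hotelling's T², standardized PCA
profiles) and generative-model evaluation metrics (FID, Inception Score,
Relative Inception Score, whole-image intensity PCA), plus a seeded texture
generator so the full pipeline runs without external histology data.
"""

from importlib import resources

from .patch import ImagePatch, discover_images, load_patch, save_patch
from .preprocess import (
    IntensityOutlierFilter,
    PatchPreprocessor,
    mean_rgb_intensity,
    preprocess_for_shrqa,
    remove_intensity_outliers,
    tile_image,
    tissue_fraction,
)
from .shrqa import (
    ShrqaConfig,
    ShrqaExtractor,
    dwt2_haar,
    embed_trajectory,
    hilbert_flatten,
    ifs_project,
    quadtree_partition,
    quantify_recurrence,
    shrqa_features,
)
from .stats import (
    LassoFeatureSelector,
    PCAProfile,
    classification_accuracy,
    hotelling_t2,
    lasso_select,
    load_qc_table,
    pca_summary,
    qc_pass_rate,
    radar_profile,
)
from .metrics import (
    fit_embedding_gaussian,
    frechet_distance,
    inception_score,
    intensity_pca,
    mock_classifier_probs,
    mock_embedder,
    relative_inception_score,
)
from .texture import (
    PatternClass,
    TextureSpec,
    default_templates,
    generate_cohort,
    generate_outlier_image,
    generate_texture_patch,
    perturb_cohort,
    perturb_patch,
    write_patch_set,
)
from .pipeline import run_compare, run_demo, summarize_qc

__version__ = "0.1.0"


def packaged_qc_table_path():
    """Path to the packaged pathologist QC table (8 tissues x 20 P/F grades)."""
    return resources.files("spatialrqa").joinpath("data/qc_table.csv")
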