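import pytest

from cvatlas import (
    AtlasDesign,
    GroupMatrix,
    default_ground_truth,
    gen_mtdr,
    gen_plate,
    normalize_table,
    quantify_plate,
)

SMALL_TISSUES = ("Liver", "Heart atrium", "Tongue", "Testes", "Fallopian tubes")


@pytest.fixture(scope="session")
def small_design():
    return AtlasDesign(tissues=SMALL_TISSUES, n_per_group=4)


@pytest.fixture(scope="session")
def zero_noise_truth(small_design):
    return default_ground_truth(small_design, seed=11)


@pytest.fixture(scope="session")
def zero_noise_atlas(small_design, zero_noise_truth):
    """(traces, readings, normalized, matrix) for a small zero-noise atlas."""
    traces, _ = gen_plate(small_design, zero_noise_truth)
    readings = gen_mtdr(small_design, zero_noise_truth)
    records = quantify_plate(traces, small_design.schedule)
    normalized = normalize_table(records, readings)
    return traces, readings, normalized, GroupMatrix.from_normalized(normalized)


@pytest.fixture(scope="session")
def noisy_atlas_matrix():
    """GroupMatrix from a moderately noisy default-truth atlas (8 tissues)."""
    design = AtlasDesign(
        tissues=("Liver", "Heart atrium", "Tongue", "gWAT", "Spleen",
                 "Diaphragm", "Ileum", "Skin"),
        n_per_group=10,
    )
    truth = default_ground_truth(
        design, seed=7, noise_cv_ar=0.15, noise_sd_fluor=20.0
    )
    traces, _ = gen_plate(design, truth)
    records = quantify_plate(traces, design.schedule)
    normalized = normalize_table(records, gen_mtdr(design, truth))
    return GroupMatrix.from_normalized(normalized), truth
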