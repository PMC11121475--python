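import numpy as np
import pytest

from thermofract.architecture import ArchitectureSpec, LayerSpec
from thermofract.synthetic import CohortConfig, generate_cohort
from thermofract.preprocess import preprocess_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4 fracture + 4 sprain participants, 5 frames each, small ROIs."""
    config = CohortConfig(
        n_fracture=4, n_sprain=4, frames_per_participant=5,
        roi_side_range=(40, 70), seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_spectra(small_cohort):
    return preprocess_cohort(small_cohort)


def tiny_architecture(input_hw=(8, 8), filters=4, with_batchnorm=True):
    """Minimal conv net for gradient checks and toy training."""
    layers = [LayerSpec("input", "Input"),
              LayerSpec("conv2d", "Conv_1", filters=filters, in_channels=1)]
    if with_batchnorm:
        layers.append(LayerSpec("batchnorm", "Batchnorm_1", channels=filters))
    layers.append(LayerSpec("relu", "ReLU_1"))
    layers.append(LayerSpec("maxpool", "MaxPool_1"))
    h, w = input_hw[0] // 2, input_hw[1] // 2
    layers.append(LayerSpec("fully_connected", "FC",
                            in_features=filters * h * w, out_features=2))
    layers.append(LayerSpec("softmax", "Softmax"))
    layers.append(LayerSpec("classification", "Classification"))
    return ArchitectureSpec(tuple(layers), input_shape=(*input_hw, 1))
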