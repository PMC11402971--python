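import numpy as np
import pytest

from condviab.featurization import CompoundRecord


@pytest.fixture(scope="session")
def ethanol():
    return CompoundRecord(compound_id="ethanol", smiles="CCO")


@pytest.fixture(scope="session")
def tiny_training_set():
    """Small fully synthetic regression problem: 6 cells x 4 compounds on an
    8-point grid, viability from planted Hill curves.  Shared across model
    and attribution tests."""
    from condviab.benchmark import make_benchmark_data
    from condviab.synthetic import SyntheticConfig

    cfg = SyntheticConfig(n_cell_lines=8, n_genes=30, n_compounds=8,
                          n_moa_classes=2, targets_per_class=2,
                          noise_sd=0.02, seed=11)
    return make_benchmark_data(5, config=cfg, n_test_cells=2)


@pytest.fixture(scope="session")
def tiny_model(tiny_training_set):
    """A small trained film-variant regressor over the tiny cohort."""
    from condviab.model import ViabilityRegressor

    d = tiny_training_set
    est = ViabilityRegressor(variant="film", gene_encoder_widths=(24,),
                             compound_encoder_widths=(16,), embedding_dim=12,
                             n_film_layers=2, dropout=0.0, lr=3e-3,
                             batch_size=128, max_epochs=15, patience=15,
                             random_state=0)
    est.fit(d.X[d.train_mask], d.y[d.train_mask],
            groups=d.row_cells[d.train_mask])
    return est
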