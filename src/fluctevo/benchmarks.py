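"""Planted-truth recovery harnesses.

These run the full generator -> analysis chain on synthetic data with
known ground truth and score how much of that truth the pipeline recovers.
They back both the test suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fluctevo.biolog import (
    PCAModel,
    ancestor_centroids,
    classify_restoration,
    fit_pca,
    normalize_plates,
)
from fluctevo.synthetic_data import default_biolog_config, generate_biolog_plates
from fluctevo.synthetic_data.plates import BiologPlateSet

__all__ = ["restoration_chain", "restoration_recovered_fraction"]


def restoration_chain(
    seed: int, effect_size: float = 5.0, n_components: int | str = 3
) -> tuple[BiologPlateSet, PCAModel, pd.DataFrame]:
    """Generate plates -> normalise -> PCA -> centroids -> restoration calls."""
    cfg = default_biolog_config(seed=seed, effect_size=effect_size)
    plates = generate_biolog_plates(cfg)
    features = normalize_plates(plates.plates)
    model = fit_pca(features, n_components=n_components)
    meta = plates.metadata
    ancestors = meta.index[meta.role == "ancestor"]
    evolved = meta.index[meta.role == "evolved"]
    centroids = ancestor_centroids(
        model, model.scores.loc[ancestors], meta.loc[ancestors], group_col="lineage"
    )
    group_of = pd.Series(
        {s: cfg.lineage_of.get(s, "606") for s in meta["strain_id"].unique()}
    )
    calls = classify_restoration(
        model.scores.loc[evolved], meta.loc[evolved], centroids, group_of=group_of
    )
    return plates, model, calls


def restoration_recovered_fraction(
    plates: BiologPlateSet, model: PCAModel, calls: pd.DataFrame
) -> float:
    """Fraction of planted categories recovered on their carrying component.

    Each plant lives along one of the generator's ground-truth directions
    (the plasticity axis u1, or u2 for "novel" plants); the PCA component
    carrying it is identified by loading alignment and the call on that
    component is compared with the planted category.
    """
    loadings = model.loadings.to_numpy()
    c1 = model.loadings.columns[np.argmax(np.abs(plates.truth["u1"] @ loadings))]
    c2 = model.loadings.columns[np.argmax(np.abs(plates.truth["u2"] @ loadings))]
    by_key = calls.set_index(["strain_id", "temperature_C", "component"])["category"]
    hits = [
        by_key.loc[(strain, temp, c2 if category == "novel" else c1)] == category
        for (strain, temp), category in plates.truth["planted"].items()
    ]
    return float(np.mean(hits))
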