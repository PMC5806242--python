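import numpy as np
import pandas as pd
import pytest

from chemopls import (
    MetaboliteTable,
    SyntheticConfig,
    default_metabolite_meta,
)

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


def make_table(values, sample_ids=None, metabolite_ids=None, *, fraction="pellet",
               class_labels=None, media_controls=None, is_metabolite=None,
               platform="GC", cell_lines=None):
    """Hand-build a small MetaboliteTable for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"m{j + 1}" for j in range(m)]
    media_controls = media_controls or [False] * n
    if class_labels is None:
        class_labels = [None if mc else ("pos" if i < n // 2 else "neg")
                        for i, mc in enumerate(media_controls)]
    vdf = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                       columns=pd.Index(metabolite_ids, name="metabolite_id"))
    smeta = pd.DataFrame(
        {
            "class_label": class_labels,
            "fraction": fraction,
            "platform": platform,
            "cell_line": cell_lines or ["line"] * n,
            "is_media_control": media_controls,
            "treatment": None,
        },
        index=vdf.index,
    )
    mmeta = default_metabolite_meta(metabolite_ids)
    if is_metabolite is not None:
        mmeta.loc[is_metabolite, "is_internal_standard"] = True
    return MetaboliteTable(vdf, smeta, mmeta)


@pytest.fixture
def small_table():
    return make_table([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])


@pytest.fixture
def strong_effect_config():
    """Well-separated two-class design: 10 planted metabolites at delta = 2,
    18 samples per class, on a 400-metabolite panel."""
    return SyntheticConfig(
        n_lines_per_class=3,
        n_reps_per_line=6,
        n_media_controls=0,
        n_metabolites=400,
        planted_effects={j: 2.0 for j in range(10)},
        pathway_blocks=[],
        seed=0,
    )


@pytest.fixture
def null_config():
    """No class effect, no orthogonal factor: 12 samples per class."""
    return SyntheticConfig(
        n_lines_per_class=2,
        n_reps_per_line=6,
        n_media_controls=0,
        n_metabolites=80,
        planted_effects={},
        pathway_blocks=[],
        orthogonal_strength=0.0,
        seed=0,
    )
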