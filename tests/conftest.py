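import numpy as np
import pandas as pd
import pytest

from mirnome import synthetic


def make_annotation(class_sizes: dict[str, int], control: str = "normal",
                    icd10: dict[str, str] | None = None,
                    excluded: tuple[str, ...] = ()) -> pd.DataFrame:
    """Minimal annotation table for hand-built matrices."""
    icd10 = icd10 or {}
    rows = []
    i = 0
    for lab, n in class_sizes.items():
        for _ in range(n):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "class_label": lab,
                    "icd10": icd10.get(lab, ""),
                    "is_control": lab == control,
                    "include_pooled": lab not in excluded,
                    "include_pairwise": lab not in excluded,
                    "center": "",
                }
            )
    return pd.DataFrame(rows)


def make_matrix(values: np.ndarray, annotation: pd.DataFrame,
                feature_ids=None) -> pd.DataFrame:
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    m = pd.DataFrame(values, index=feature_ids, columns=annotation["sample_id"].tolist())
    m.index.name = "feature_id"
    return m


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the full 22-cohort, 848-feature planted study."""
    design = synthetic.default_study_design()
    signal = synthetic.default_signal_spec(design)
    matrix, annotation = synthetic.generate_cohort(design, signal, seed=11)
    return design, signal, matrix, annotation
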