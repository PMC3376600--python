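import numpy as np
import pandas as pd
import pytest

from goosevox.gfcc import FEATURE_COLUMNS
from goosevox.labels import CLASS_ORDER


def make_feature_table(
    class_means: dict,
    n_sequences: int = 20,
    frames_per_sequence: int = 3,
    noise: float = 0.5,
    n_features: int = 21,
    seed: int = 0,
    day_tags: tuple = ("day1", "day2"),
) -> pd.DataFrame:
    """Gaussian feature clouds shaped like an extracted feature table.

    ``class_means`` maps behaviour label → mean vector (padded with zeros
    to ``n_features``).  Sequences alternate between day tags; each
    sequence contributes ``frames_per_sequence`` rows around its own
    centre so frames of one sequence are correlated, as in real data.
    """
    rng = np.random.default_rng(seed)
    records = []
    for label, mean in class_means.items():
        mean = np.pad(np.asarray(mean, float), (0, n_features - len(mean)))
        for s in range(n_sequences):
            day = day_tags[s % len(day_tags)]
            seq_id = f"{label}-{s:04d}"
            center = mean + rng.normal(0, noise, n_features)
            for f in range(frames_per_sequence):
                row = center + rng.normal(0, noise / 3, n_features)
                rec = {"clip": day, "sequence_id": seq_id, "frame_index": f,
                       "day_tag": day, "label": label}
                rec.update(zip(FEATURE_COLUMNS[:n_features], row))
                records.append(rec)
    cols = ["clip", "sequence_id", "frame_index", "day_tag", "label"]
    cols += FEATURE_COLUMNS[:n_features]
    return pd.DataFrame.from_records(records, columns=cols)


@pytest.fixture(scope="session")
def separated_features() -> pd.DataFrame:
    """Three well-separated classes (inter-mean distance >> spread)."""
    means = {
        CLASS_ORDER[0]: [6.0, 0.0, 0.0],
        CLASS_ORDER[1]: [0.0, 6.0, 0.0],
        CLASS_ORDER[2]: [0.0, 0.0, 6.0],
    }
    return make_feature_table(means, n_sequences=24, noise=0.5, seed=7)
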