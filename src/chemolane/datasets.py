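"""Small built-in example datasets.

Everything here is synthetic: constructed to be representative of the
kinds of tables the assays produce, for examples, docs, and worked
checks — none of it is measured data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synthetic_control_indices", "synthetic_phenotype_table"]


def synthetic_control_indices() -> tuple[np.ndarray, np.ndarray]:
    """Synthetic positive/negative control Chemotaxis Index replicates.

    A stand-in replicate table (percent per lane, six replicates per
    control group) constructed so its separation statistics are typical of
    a well-behaved lane-assay screen: a strongly chemotactic positive
    control near 30 and a near-zero negative control, giving a Z-factor of
    about 0.69 — in the "excellent assay" regime (Z' > 0.5).  Synthetic
    values, not measurements.

    Returns (positive, negative) arrays.
    """
    positive = np.array([30.3, 26.6, 32.7, 33.2, 29.9, 29.4])
    negative = np.array([1.4, 0.7, 2.4, 1.1, 1.5, 0.9])
    return positive, negative


def synthetic_phenotype_table() -> pd.DataFrame:
    """Synthetic strain-by-phenotype table for the clustering example.

    Six hypothetical strains scored on four assays (arbitrary but
    unit-plausible values): a wild-type-like group, a chemotaxis-deficient
    group with intact motility, and a paralyzed outlier.  Synthetic values,
    not measurements.
    """
    return pd.DataFrame(
        {
            "chemotaxis_index": [29.5, 31.2, 4.1, 3.2, 27.8, 0.9],
            "photoshock_response": [0.95, 0.97, 0.94, 0.12, 0.96, 0.05],
            "symmetric_incidences": [0.085, 0.081, 0.088, 0.053, 0.079, 0.002],
            "swim_speed": [104.0, 98.0, 101.0, 95.0, 110.0, 8.0],
        },
        index=["WT-A", "WT-B", "chemo-1", "chemo-2", "WT-C", "paralyzed"],
    )
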