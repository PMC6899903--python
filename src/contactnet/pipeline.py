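"""Convenience wiring: alignment -> features -> training example.

Kept separate from the feature modules so the CLI, the tests and the
synthetic benchmark all build inputs through exactly one code path.
"""

from __future__ import annotations

import numpy as np

from .augment import TrainingExample
from .features import FeatureTensor, ResidueFeatures, assemble_features
from .msa_io import Msa
from .pair_features import pair_matrices
from .synthetic import SyntheticFamily, residue_features


def features_from_msa(
    msa: Msa,
    res: ResidueFeatures,
    external: dict[str, np.ndarray] | None = None,
    weighted: bool = True,
) -> FeatureTensor:
    """Full 501-channel assembly from an alignment and per-residue features."""
    pm = pair_matrices(msa, weighted=weighted)
    return assemble_features(msa, res, pm, external)


def family_to_example(
    family: SyntheticFamily,
    with_shallow_pair: bool = True,
    weighted: bool = True,
) -> TrainingExample:
    """Build a training example (deep tensor, optionally paired shallow tensor).

    External coupling maps are not produced by the synthetic generator and
    are zero-filled.
    """
    import warnings

    res = residue_features(family.protein, family.msa_deep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # missing external maps are expected here
        x = features_from_msa(family.msa_deep, res, weighted=weighted)
        x_alt = None
        if with_shallow_pair:
            res_sh = residue_features(family.protein, family.msa_shallow)
            x_alt = features_from_msa(family.msa_shallow, res_sh, weighted=weighted)
    return TrainingExample(
        x=x,
        y=family.protein.contact_map.astype(np.int8),
        loop_mask=family.protein.loop_mask,
        x_alt=x_alt,
    )
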