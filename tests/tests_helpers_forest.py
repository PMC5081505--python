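"""Shared helper: hand-built root-only survival forests for exact checks."""

import numpy as np

from icuforecast import RsfParams
from icuforecast._tree import Tree
from icuforecast.survival_forest import SurvivalForestModel


def single_leaf_survival_model(chfs, n_features=1):
    """Forest whose trees are single terminal nodes with the given CHFs."""
    trees = [
        Tree(
            feature=np.array([-1]),
            threshold=np.array([0.0]),
            left=np.array([-1]),
            right=np.array([-1]),
            leaf_id=np.array([0]),
        )
        for _ in chfs
    ]
    return SurvivalForestModel(
        trees=trees,
        leaf_chfs=[[chf] for chf in chfs],
        oob_indices=[np.empty(0, int) for _ in chfs],
        params=RsfParams(n_trees=len(chfs)),
        feature_names=[f"f{j}" for j in range(n_features)],
        n_train=0,
        event_times=np.array([1.0]),
    )
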