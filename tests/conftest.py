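import numpy as np
import pandas as pd
import pytest

from eegagree.preprocess import EpochSet


def make_epochs(data, fs=512.0, tmin=-0.1, labels=None, conditions=None,
                follows_deviant=None, is_habituation=None, system="wet",
                layout_name=None, eog=(), mastoids=()):
    """Build an EpochSet from a raw (trials, channels, samples) array."""
    data = np.asarray(data, float)
    n_tr, n_ch, _ = data.shape
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    conditions = conditions if conditions is not None else ["standard"] * n_tr
    info = pd.DataFrame(
        dict(
            condition=list(conditions),
            is_habituation=list(is_habituation) if is_habituation is not None
            else [False] * n_tr,
            follows_deviant=list(follows_deviant) if follows_deviant is not None
            else [False] * n_tr,
            onset_sample=np.arange(n_tr) * data.shape[2],
        )
    )
    return EpochSet(
        data=data, fs=fs, tmin=tmin, channel_labels=list(labels), info=info,
        kept_mask=np.ones(n_tr, bool), system=system, layout_name=layout_name,
        eog_channels=list(eog), mastoids=list(mastoids),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
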