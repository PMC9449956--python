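"""Small reference fixtures shipped with the package."""

from importlib import resources

import pandas as pd

from ..evaluation import ConfusionMatrix


def reference_confusion_matrix() -> ConfusionMatrix:
    """The reported held-out ensemble confusion matrix of the original
    clinical study (five severity categories present), used as a
    metric-oracle input."""
    with resources.files(__package__).joinpath("reference_confusion.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return ConfusionMatrix(
        classes=tuple(str(c) for c in df.columns), counts=df.to_numpy()
    )
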