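"""Model checkpoints as .npz archives (parameters + width profile)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .network import HourglassModel, build_model

PathLike = Union[str, Path]


def save_model(model: HourglassModel, path: PathLike,
               widths: Sequence[int]) -> None:
    state = model.state_dict()
    np.savez_compressed(path, __widths__=np.asarray(widths, dtype=np.int64), **state)


def load_model(path: PathLike) -> HourglassModel:
    with np.load(path) as data:
        widths = tuple(int(v) for v in data["__widths__"])
        model = build_model(widths=widths)
        model.load_state_dict({k: data[k] for k in data.files if k != "__widths__"})
    return model
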