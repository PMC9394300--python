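"""The three expression-value transformations compared by the pipeline.

* ``unprocessed`` — identity on the FPKM values.
* ``log10``      — entrywise log10(x), with entries exactly equal to 0 kept
  at 0. Entries in (0, 1) therefore map to negative values; only exact
  zeros are remapped. (An off-by-default ``clip_sub_one`` option instead
  sets every x < 1 to 0.)
* ``log10p1``    — entrywise log10(x + 1); always >= 0, zero iff x == 0.

The divergence between log10 and log10p1 on sub-1 FPKM values, and between
either and the heavy-tailed unprocessed values, is exactly what makes the
downstream embeddings differ.
"""

from __future__ import annotations

import numpy as np

from .types import ExpressionMatrix, ValidationError

__all__ = ["TRANSFORMS", "TRANSFORM_DISPLAY", "apply_transform"]

TRANSFORMS = ("unprocessed", "log10", "log10p1")

# Display strings for UTMC legends.
TRANSFORM_DISPLAY = {
    "unprocessed": "unprocessed",
    "log10": "log10",
    "log10p1": "log10 + 1",
}


def apply_transform(
    X: ExpressionMatrix | np.ndarray,
    kind: str,
    clip_sub_one: bool = False,
) -> np.ndarray:
    """Return a transformed copy of the expression values.

    Parameters
    ----------
    X : ExpressionMatrix or ndarray
        Nonnegative genes x samples values. Never mutated.
    kind : {"unprocessed", "log10", "log10p1"}
    clip_sub_one : bool
        Only meaningful for ``log10``: if True, all values < 1 (not just
        exact zeros) are set to 0 instead of retaining negative logs.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if not np.isfinite(values).all():
        raise ValidationError("expression values contain non-finite entries")
    if (values < 0).any():
        idx = np.argwhere(values < 0)[0]
        raise ValidationError(f"negative expression value at index {tuple(idx)}")
    if kind not in TRANSFORMS:
        raise ValidationError(
            f"unknown transform {kind!r}; expected one of {TRANSFORMS}"
        )

    if kind == "unprocessed":
        return values.copy()
    if kind == "log10p1":
        return np.log10(values + 1.0)
    # log10 with the zero rule
    out = np.zeros_like(values)
    if clip_sub_one:
        pos = values >= 1.0
    else:
        pos = values > 0.0
    out[pos] = np.log10(values[pos])
    return out
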