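"""Shared numerical kernels."""

from __future__ import annotations

import numpy as np

_SMALL = 1e-6


def scaled_pfix(s):
    """Scaled fixation probability factor ``s / (1 - exp(-s))``.

    ``s`` is the Malthusian (log-)fitness difference of the mutant over the
    resident, already scaled by population size.  The factor tends to 1 as
    ``s -> 0`` (neutral limit), to ``s`` for strongly beneficial and to
    ``|s| exp(-|s|)`` for strongly deleterious mutations.  Evaluated as
    ``s / -expm1(-s)`` with a second-order series around zero, which is
    stable for large positive and negative arguments alike.
    """
    s = np.asarray(s, dtype=float)
    small = np.abs(s) < _SMALL
    # series: s/(1-e^-s) = 1 + s/2 + s^2/12 + O(s^4)
    series = 1.0 + s / 2.0 + s * s / 12.0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        exact = s / (-np.expm1(-np.where(small, 1.0, s)))
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)
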