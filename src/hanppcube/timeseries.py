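"""Epoch-snapshot interpolation shared by readers and the generator."""

from __future__ import annotations

import numpy as np

__all__ = ["make_epoch_series", "footprint_for_year"]


def make_epoch_series(values_at_epochs: dict, years) -> dict:
    """Annual series from epoch snapshots: linear interpolation between
    epochs, constant extrapolation before the first and after the last.

    Values may be scalars or arrays; epochs must be unique.
    """
    if not values_at_epochs:
        raise ValueError("need at least one epoch")
    epochs = sorted(values_at_epochs)
    if len(epochs) != len(set(int(e) for e in epochs)):
        raise ValueError("duplicate epochs")
    out = {}
    for y in years:
        if y <= epochs[0]:
            out[y] = values_at_epochs[epochs[0]]
        elif y >= epochs[-1]:
            out[y] = values_at_epochs[epochs[-1]]
        else:
            hi = min(e for e in epochs if e >= y)
            lo = max(e for e in epochs if e <= y)
            if hi == lo:
                out[y] = values_at_epochs[lo]
            else:
                w = (y - lo) / (hi - lo)
                out[y] = (1 - w) * values_at_epochs[lo] + w * values_at_epochs[hi]
    return out


def footprint_for_year(footprint: dict[int, np.ndarray], year: int) -> np.ndarray:
    """Human-footprint layer for a year, bridging the 1993 source change.

    The 1993 layer comes from a different product than the annual series
    from 2000 on; continuity is established by counting a cell as
    footprint-zero in 1993 only if the 1993/2000 mean is below 1 *and*
    the 2000 value is zero.  Between the adjusted 1993 layer and 2000 the
    index is interpolated linearly; outside the observed span values are
    held constant.
    """
    if year >= 2000:
        series = {y: footprint[y] for y in footprint if y >= 2000}
        return np.asarray(make_epoch_series(series, [year])[year])
    f93, f00 = footprint[1993], footprint[2000]
    adj = f93.copy()
    zero93 = (0.5 * (f93 + f00) < 1.0) & (f00 == 0)
    adj[zero93] = 0.0
    adj[~zero93 & (adj == 0)] = 1.0  # zero only where the bridged rule says so
    if year <= 1993:
        return adj
    w = (year - 1993) / (2000 - 1993)
    return (1 - w) * adj + w * f00
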