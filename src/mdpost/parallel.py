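"""Frame-parallel execution contract.

Every trajectory analysis maps an independent function over frame indices
and reduces the results in frame order, so the output is bit-identical for
any worker count (including 1). The thread backend is used because the
per-frame work is numpy-dominated and the closures capture live trajectory
objects.
"""

from __future__ import annotations

from joblib import Parallel, delayed


def map_frames(func, n_frames: int, n_workers: int = 1) -> list:
    """Apply ``func(k)`` for k in 0..n_frames-1, preserving frame order."""
    if n_workers <= 1:
        return [func(k) for k in range(n_frames)]
    return Parallel(n_jobs=n_workers, backend="threading")(
        delayed(func)(k) for k in range(n_frames))
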