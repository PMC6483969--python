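"""Small shared helpers: seeding, hashing, validation."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np


def derive_seed(master: int, *key: int) -> int:
    """Derive a child seed from a master seed and an integer key path.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so children are
    statistically independent of each other and of the master stream.
    """
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, np.uint64)[0])


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def kruskal_pvalue(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis p with tie correction; p = 1 when all values coincide
    (scipy's tie correction degenerates there)."""
    from scipy import stats

    allv = np.concatenate(groups)
    if np.unique(allv).size <= 1:
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def check_proportion(value: float, name: str, *, lo: float = 0.0, hi: float = 1.0,
                     inclusive_lo: bool = True, inclusive_hi: bool = True) -> None:
    ok_lo = value >= lo if inclusive_lo else value > lo
    ok_hi = value <= hi if inclusive_hi else value < hi
    if not (ok_lo and ok_hi):
        lb = "[" if inclusive_lo else "("
        rb = "]" if inclusive_hi else ")"
        raise ValueError(f"{name} must lie in {lb}{lo}, {hi}{rb}; got {value!r}")
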