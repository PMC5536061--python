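"""Small shared helpers: reporting-grade rounding and file hashing."""

from __future__ import annotations

import hashlib
import math
from pathlib import Path


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed tables).

    ``numpy.round`` rounds half to even, which does not match how the
    reference tables were formatted; reporting code in this package goes
    through this helper instead.  The raw (unrounded) statistics are always
    kept alongside.
    """
    if math.isnan(x):
        return math.nan
    scale = 10.0 ** ndigits
    r = math.floor(abs(x) * scale + 0.5) / scale
    return math.copysign(r, x)


def round_half_away_int(x: float) -> int:
    return int(round_half_away(x, 0))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
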