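"""Sleep-stage vocabulary and hypnogram label handling.

The package scores sleep in the 5-class AASM vocabulary: Wake (W), the three
non-REM depths N1–N3, and REM.  Stages are represented internally as integer
codes 0–4 in the fixed order ``(W, N1, N2, N3, REM)``; every matrix in the
package (transition, emission, confusion) uses this order for both axes.

Scorer files in the older R&K convention use the vocabulary
``{W, 1, 2, 3, 4, R, M, ?}``; :func:`parse_hypnogram_labels` maps it to the
5-class scheme, merging stage 4 into N3 and excluding Movement/Unknown epochs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Fixed stage order used for every 5-vector / 5x5 matrix in the package.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

N_STAGES = len(STAGES)

STAGE_TO_CODE: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Aliases accepted when reading external label files (R&K and AASM spellings).
_ALIASES: dict[str, str] = {
    "W": "W",
    "WAKE": "W",
    "0": "W",
    "N1": "N1",
    "1": "N1",
    "S1": "N1",
    "N2": "N2",
    "2": "N2",
    "S2": "N2",
    "N3": "N3",
    "3": "N3",
    "S3": "N3",
    "N4": "N3",  # R&K stage 4 merged into N3
    "4": "N3",
    "S4": "N3",
    "R": "REM",
    "REM": "REM",
    "5": "REM",
}

#: Tokens marking epochs excluded from scoring.
_EXCLUDED: frozenset[str] = frozenset({"M", "MOVEMENT", "?", "UNKNOWN", "U"})


def stage_code(label: int | str) -> int:
    """Return the integer stage code for ``label`` (code, name, or alias)."""
    if isinstance(label, (int, np.integer)):
        if not 0 <= int(label) < N_STAGES:
            raise ValueError(f"stage code out of range: {label!r}")
        return int(label)
    token = str(label).strip().upper()
    if token in _EXCLUDED:
        raise ValueError(f"label {label!r} marks an excluded epoch, not a stage")
    try:
        return STAGE_TO_CODE[_ALIASES[token]]
    except KeyError:
        raise ValueError(f"unrecognised sleep stage label: {label!r}") from None


def encode_stages(labels: Iterable[int | str]) -> np.ndarray:
    """Vector of integer stage codes for a sequence of labels."""
    return np.asarray([stage_code(lab) for lab in labels], dtype=np.int64)


def decode_stages(codes: Sequence[int] | np.ndarray) -> list[str]:
    """Stage names for a vector of integer codes."""
    return [STAGES[stage_code(int(c))] for c in codes]


def parse_hypnogram_labels(
    lines: Iterable[str], *, keep_excluded: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Parse a one-label-per-line hypnogram file into stage codes.

    Parameters
    ----------
    lines
        Iterable of text lines; blank lines and ``#`` comments are skipped.
        Each remaining line holds one stage token, optionally preceded by an
        epoch index column (ignored).
    keep_excluded
        If False (default), Movement/Unknown epochs are dropped; if True they
        are kept as code ``-1``.

    Returns
    -------
    codes, kept_indices
        ``codes`` are the stage codes; ``kept_indices`` are the 0-based epoch
        positions of the returned codes in the original file, so signals can
        be subset consistently.
    """
    codes: list[int] = []
    kept: list[int] = []
    pos = 0
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        token = line.split(",")[-1].split()[-1]
        idx = pos
        pos += 1
        if token.strip().upper() in _EXCLUDED:
            if keep_excluded:
                codes.append(-1)
                kept.append(idx)
            continue
        codes.append(stage_code(token))
        kept.append(idx)
    return np.asarray(codes, dtype=np.int64), np.asarray(kept, dtype=np.int64)


def read_hypnogram(path: str | Path, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    """Read a hypnogram text/CSV file (one stage per line)."""
    with open(path) as fh:
        return parse_hypnogram_labels(fh, **kwargs)


def write_hypnogram(path: str | Path, codes: Sequence[int] | np.ndarray) -> None:
    """Write stage codes as a one-stage-name-per-line text file."""
    with open(path, "w") as fh:
        for name in decode_stages(codes):
            fh.write(name + "\n")
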