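"""Row/column speller decoding from per-flash target scores.

The 6x6 speller flashes each of its 6 columns (codes 1-6) and 6 rows
(codes 7-12) once per repetition, 15 repetitions per character.  The
classifier assigns each flash a probability of containing a P300.  To
decode a character, the scores are summed per code over the repetitions
used; the best-scoring column and the best-scoring row select a cell of
the matrix.  Ties break toward the lowest code, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_LAYOUT",
    "SpellerSession",
    "codes_for_character",
    "decode_character",
    "character_accuracy",
    "score_session",
]

#: Classic Farwell-Donchin 6x6 layout: A-Z row-major, then 1-9 and space.
DEFAULT_LAYOUT = [
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
]


@dataclass
class SpellerSession:
    """Flash codes, per-flash scores and ground truth for one session.

    ``flash_codes`` has shape (n_characters, n_repetitions, 12), each
    repetition a permutation of 1..12.  ``scores`` (same shape, in [0, 1])
    holds the classifier's target probability per flash; it may be None
    until the epochs have been scored.
    """

    flash_codes: np.ndarray
    scores: np.ndarray | None
    truth: str
    matrix_layout: list[str]

    @property
    def n_characters(self) -> int:
        return self.flash_codes.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.flash_codes.shape[1]


def codes_for_character(char: str, layout: list[str] = DEFAULT_LAYOUT) -> tuple[int, int]:
    """(row_code, column_code) of a symbol: columns 1-6, rows 7-12."""
    for r, row in enumerate(layout):
        c = row.find(char)
        if c >= 0:
            return r + 7, c + 1
    raise ValueError(f"character {char!r} not in speller layout")


def _code_sums(scores: np.ndarray, flash_codes: np.ndarray, repetitions_used: int) -> np.ndarray:
    """Sum of scores per code (index 0 -> code 1, ..., 11 -> code 12)."""
    scores = np.asarray(scores, dtype=float)
    flash_codes = np.asarray(flash_codes, dtype=int)
    if scores.shape != flash_codes.shape:
        raise ValueError(f"scores shape {scores.shape} != flash codes shape {flash_codes.shape}")
    n_reps = flash_codes.shape[0]
    if not 1 <= repetitions_used <= n_reps:
        raise ValueError(f"repetitions_used must be in [1, {n_reps}], got {repetitions_used}")
    sums = np.zeros(12)
    for rep in range(repetitions_used):
        codes = flash_codes[rep]
        if sorted(codes.tolist()) != list(range(1, 13)):
            raise ValueError(f"repetition {rep} does not contain each code 1-12 exactly once")
        sums[codes - 1] += scores[rep]
    return sums


def decode_character(
    scores: np.ndarray,
    flash_codes: np.ndarray,
    repetitions_used: int = 15,
    layout: list[str] = DEFAULT_LAYOUT,
) -> str:
    """Decode one character from (n_repetitions, 12) scores and codes.

    Scores are summed per code over the first ``repetitions_used``
    repetitions; the max-sum column code (1-6) and row code (7-12) index
    the layout.  np.argmax's first-maximum rule gives the lowest-code
    tie-break.
    """
    sums = _code_sums(scores, flash_codes, repetitions_used)
    col = int(np.argmax(sums[:6]))  # code col+1
    row = int(np.argmax(sums[6:]))  # code row+7
    return layout[row][col]


def character_accuracy(
    session: SpellerSession, repetitions: int | None = None
) -> tuple[float, np.ndarray]:
    """Fraction of correctly decoded characters, plus the accuracy curve
    over repetitions_used = 1..n_repetitions.

    Returns ``(accuracy, curve)`` where ``accuracy`` uses ``repetitions``
    repetitions (default: all) and ``curve[r-1]`` is the accuracy with the
    first r repetitions.
    """
    if session.scores is None:
        raise ValueError("session has no scores; run the classifier first")
    if len(session.truth) != session.n_characters:
        raise ValueError(
            f"truth has {len(session.truth)} characters but session has {session.n_characters}"
        )
    n_reps = session.n_repetitions
    repetitions = n_reps if repetitions is None else repetitions
    curve = np.zeros(n_reps)
    for r in range(1, n_reps + 1):
        correct = sum(
            decode_character(session.scores[ci], session.flash_codes[ci], r, session.matrix_layout)
            == session.truth[ci]
            for ci in range(session.n_characters)
        )
        curve[r - 1] = correct / session.n_characters
    return float(curve[repetitions - 1]), curve


def score_session(classifier, epoch_set, session: SpellerSession) -> SpellerSession:
    """Fill a session's scores with the classifier's target probabilities.

    ``epoch_set`` must hold the session's epochs in flash order
    (character-major, then repetition, then flash position), as produced
    by the P300 session simulator.
    """
    proba = classifier.predict_proba(epoch_set.epochs)
    target_col = int(np.flatnonzero(classifier.classes_ == 1)[0])
    scores = proba[:, target_col].reshape(session.flash_codes.shape)
    return SpellerSession(
        flash_codes=session.flash_codes,
        scores=scores,
        truth=session.truth,
        matrix_layout=session.matrix_layout,
    )
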