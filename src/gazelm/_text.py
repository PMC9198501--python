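"""Word-form normalization shared by accuracy scoring and table merging.

Cloze-accuracy scoring, top-k accuracy and frequency lookup all compare
word forms case-insensitively after stripping punctuation and whitespace,
so that human and model predictions are scored like-for-like.
"""

from __future__ import annotations

import string

# ASCII punctuation plus the curly quotes/dashes common in published passages.
_PUNCT = string.punctuation + "‘’“”–—…"
_TABLE = str.maketrans("", "", _PUNCT)


def normalize_word(word: str) -> str:
    """Lower-case, punctuation-stripped, whitespace-stripped form of ``word``."""
    return word.strip().translate(_TABLE).lower()


def is_sentence_final(surface: str) -> bool:
    """Whether a surface form ends a sentence (., ! or ?, allowing closing quotes)."""
    stripped = surface.rstrip("\"')]’”")
    return stripped.endswith((".", "!", "?"))


def letter_count(surface: str) -> int:
    """Word length in letters: characters remaining after punctuation stripping."""
    return len(surface.strip().translate(_TABLE))
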