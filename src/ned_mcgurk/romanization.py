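"""Kana-to-Latin transliteration for free-text syllable reports.

Participants typed responses in the Latin alphabet, hiragana, or katakana.
This module ships a static lookup table covering the consonant-vowel morae
that occur as McGurk/congruent percepts plus common distractor morae.
Fuzzy matching and general-purpose Japanese romanization are deliberately
out of scope: anything the table does not cover is preserved verbatim and
ends up in the "other" response category downstream.
"""

from __future__ import annotations

import string
import unicodedata

# Longest-match lookup: multi-character morae (e.g. "ヴァ" -> "va") must be
# listed and are tried before single kana.
KANA_TO_LATIN: dict[str, str] = {
    # hiragana
    "ば": "ba", "が": "ga", "だ": "da", "た": "ta", "ぱ": "pa", "か": "ka",
    "は": "ha", "ま": "ma", "な": "na", "ら": "ra", "わ": "wa", "さ": "sa",
    "ざ": "za", "や": "ya", "あ": "a",
    # katakana
    "バ": "ba", "ガ": "ga", "ダ": "da", "タ": "ta", "パ": "pa", "カ": "ka",
    "ハ": "ha", "マ": "ma", "ナ": "na", "ラ": "ra", "ワ": "wa", "サ": "sa",
    "ザ": "za", "ヤ": "ya", "ア": "a",
    "ヴァ": "va", "ゔぁ": "va",
}

# Characters removed outright before transliteration: ASCII punctuation,
# CJK punctuation, the long-vowel mark and small tsu (gemination marks do
# not change the syllable category).
_IGNORED = set(string.punctuation) | set(string.whitespace) | {
    "、", "。", "・", "ー", "「", "」", "っ", "ッ", "　",
}

_MAX_KEY_LEN = max(len(k) for k in KANA_TO_LATIN)


def normalize_response(raw_response: str, romanization_map: dict[str, str] | None = None) -> str:
    """Normalize a raw syllable report to a lowercase Latin string.

    Unicode is NFKC-normalized and casefolded, punctuation and whitespace
    are stripped, and kana are transliterated by longest-prefix lookup in
    ``romanization_map`` (default: the shipped table). Unmapped characters
    are preserved verbatim so they route to "other" during scoring.

    Returns the empty string when nothing survives normalization; callers
    must treat such trials as flagged-invalid.
    """
    table = KANA_TO_LATIN if romanization_map is None else romanization_map
    max_len = max((len(k) for k in table), default=1)
    text = unicodedata.normalize("NFKC", raw_response).casefold()
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in _IGNORED:
            i += 1
            continue
        matched = False
        for width in range(min(max_len, len(text) - i), 0, -1):
            chunk = text[i : i + width]
            if chunk in table:
                out.append(table[chunk])
                i += width
                matched = True
                break
        if not matched:
            out.append(ch)
            i += 1
    return "".join(out)
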