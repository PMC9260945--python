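"""Small shared helpers: glyph normalization and presentation rounding."""

from __future__ import annotations

import decimal

# Published tables mix typographic minus glyphs; normalize all of them to ASCII '-'.
_MINUS_GLYPHS = {
    "−": "-",  # minus sign
    "–": "-",  # en dash
    "—": "-",  # em dash
    "‐": "-",  # hyphen
    "‑": "-",  # non-breaking hyphen
}


def normalize_minus(text: str) -> str:
    """Replace typographic minus/dash glyphs with ASCII hyphen-minus."""
    for glyph, repl in _MINUS_GLYPHS.items():
        text = text.replace(glyph, repl)
    return text


def parse_number(text: str) -> float:
    """Parse a number that may use a typographic minus glyph."""
    return float(normalize_minus(str(text).strip()))


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero (half-up), unlike banker's ``round``.

    Tables are presented with conventional half-up rounding (e.g. 1.485765
    prints as 1.4858), which ``round()`` does not guarantee.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))
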