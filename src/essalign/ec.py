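"""Truncated Enzyme Commission identifiers.

Every enzyme in the comparison method is represented by the first three
levels of its EC number (class, subclass, sub-subclass).  The fourth,
serial level is discarded because it identifies a particular substrate
rather than a type of chemistry, and the method compares kinds of
catalysis, not specific reactions.

Unresolved levels (as in ``5.x.x``) are preserved verbatim as sentinel
tokens; a sentinel compares equal only to itself and unequal to every
numeric level, which is exactly the behaviour string equality gives.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Alignment gap cell.  A gap is *not* an :class:`ECCode`; column scoring
#: treats it as one additional symbol at every EC level.
GAP = None

#: Text rendering of a gap cell in alignment files.
GAP_CHAR = "-"


@dataclass(frozen=True, slots=True)
class ECCode:
    """A three-level (truncated) EC number such as ``2.7.1``.

    Each level is stored as its text token: a positive integer for a
    resolved level or an arbitrary non-numeric sentinel (``x``) for an
    unresolved one.
    """

    level1: str
    level2: str
    level3: str

    def __post_init__(self) -> None:
        for tok in (self.level1, self.level2, self.level3):
            if not tok or "." in tok or any(c.isspace() for c in tok):
                raise ValueError(f"invalid EC level token {tok!r}")
            if tok.isdigit() and int(tok) < 1:
                raise ValueError(f"numeric EC levels must be >= 1, got {tok!r}")

    @property
    def levels(self) -> tuple[str, str, str]:
        return (self.level1, self.level2, self.level3)

    @classmethod
    def parse(cls, text: str) -> "ECCode":
        """Parse ``"2.7.1"``, ``"ec:2.7.1.40"`` or ``"5.x.x"``.

        Levels beyond the third are truncated away.
        """
        body = text.strip()
        if body.lower().startswith("ec:"):
            body = body[3:]
        tokens = body.split(".")
        if len(tokens) < 3:
            raise ValueError(f"EC number needs at least three levels: {text!r}")
        return cls(tokens[0], tokens[1], tokens[2])

    def __str__(self) -> str:
        return f"{self.level1}.{self.level2}.{self.level3}"


def parse_ec_tokens(name: str) -> list[ECCode]:
    """Extract every parseable EC code from a whitespace-separated name
    attribute (e.g. KGML ``name="ec:2.7.1.1 ec:2.7.1.2"``); tokens that do
    not look like EC numbers are ignored."""
    codes: list[ECCode] = []
    for tok in name.split():
        try:
            ec = ECCode.parse(tok)
        except ValueError:
            continue
        if ec not in codes:
            codes.append(ec)
    return codes
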