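"""Mutation-channel schemas.

A *channel* is a class of single-base substitutions; the standard SBS96
schema distinguishes the six pyrimidine-strand substitutions (C>A, C>G,
C>T, T>A, T>C, T>G) in each of the 16 possible 5'/3' flanking-base
contexts, written ``5'[ref>alt]3'`` (e.g. ``A[C>A]A``).  Channel order is
substitution-major, then context-lexicographic — the conventional ordering
of COSMIC-style signature matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import SchemaMismatchError, ValidationError

_BASES = "ACGT"
_PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_LABEL_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def parse_sbs_label(label: str) -> tuple[str, str, str, str]:
    """Split an SBS channel label into (5' base, ref, alt, 3' base).

    Labels must use the pyrimidine-strand convention (ref is C or T);
    purine-reference labels are rejected rather than strand-folded, since
    folding would require the underlying variant calls.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise SchemaMismatchError(f"malformed SBS channel label: {label!r}")
    five, ref, alt, three = m.groups()
    if ref not in "CT":
        raise SchemaMismatchError(
            f"channel label {label!r} uses a purine reference base; "
            "pyrimidine-strand labels are required"
        )
    if ref == alt:
        raise SchemaMismatchError(f"channel label {label!r} has ref == alt")
    return five, ref, alt, three


def format_sbs_label(five: str, ref: str, alt: str, three: str) -> str:
    return f"{five}[{ref}>{alt}]{three}"


@dataclass(frozen=True)
class ChannelSchema:
    """An ordered set of mutation-channel labels.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"SBS96"``.
    channels
        Ordered, unique, non-empty channel labels.
    """

    name: str
    channels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("schema name must be non-empty")
        chans = tuple(self.channels)
        if len(chans) == 0:
            raise ValidationError("schema must define at least one channel")
        if any(not c for c in chans):
            raise ValidationError("channel labels must be non-empty")
        if len(set(chans)) != len(chans):
            dupes = sorted({c for c in chans if chans.count(c) > 1})
            raise ValidationError(f"duplicate channel labels: {dupes}")
        object.__setattr__(self, "channels", chans)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(chans)})

    def __len__(self) -> int:
        return len(self.channels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index_of(self, label: str) -> int:
        """Position of ``label`` in schema order."""
        try:
            return self._index[label]
        except KeyError:
            raise SchemaMismatchError(
                f"unknown channel label {label!r} for schema {self.name}"
            ) from None

    def substitution_of(self, label: str) -> str:
        """Central substitution class of a label, e.g. ``"C>A"`` for ``A[C>A]A``."""
        if label not in self._index:
            raise SchemaMismatchError(
                f"unknown channel label {label!r} for schema {self.name}"
            )
        _, ref, alt, _ = parse_sbs_label(label)
        return f"{ref}>{alt}"

    @property
    def substitution_classes(self) -> tuple[str, ...]:
        """Distinct substitution classes in first-occurrence order."""
        seen: dict[str, None] = {}
        for c in self.channels:
            seen.setdefault(self.substitution_of(c), None)
        return tuple(seen)


def _build_sbs96() -> ChannelSchema:
    labels = [
        format_sbs_label(five, sub[0], sub[2], three)
        for sub in _PYRIMIDINE_SUBS
        for five in _BASES
        for three in _BASES
    ]
    return ChannelSchema("SBS96", tuple(labels))


#: The canonical 96-channel single-base-substitution schema.
SBS96: ChannelSchema = _build_sbs96()

_REGISTRY = {"SBS96": SBS96}


def get_schema(name: str) -> ChannelSchema:
    """Look up a built-in schema by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SchemaMismatchError(
            f"unknown schema {name!r}; built-in schemas: {sorted(_REGISTRY)}"
        ) from None
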