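"""Identifier normalization.

Literature-derived regulator tables are typographically messy: en/em dashes
inside miRNA names, mixed case ("miR-17-5p" vs "MIR17"), stray whitespace.
All identifiers entering the package pass through a single canonical form so
that the same regulator named two ways cannot silently split into two nodes:

* TF and gene symbols are upper-cased (HGNC convention).
* miRNA identifiers are lower-cased ("mir-17-5p").
* Unicode dashes (en, em, minus, figure dash) become ASCII hyphens.

Precursor-to-arm matching (e.g. "mir-17" naming both arms) is never implicit;
an explicit alias table must be supplied where it is wanted.
"""

from __future__ import annotations

_DASHES = str.maketrans({c: "-" for c in "‐‑‒–—―−"})

TF = "TF"
MIRNA = "miRNA"
GENE = "gene"
NODE_CLASSES = (TF, MIRNA, GENE)

_CLASS_ALIASES = {
    "tf": TF,
    "mirna": MIRNA,
    "mir": MIRNA,
    "microrna": MIRNA,
    "gene": GENE,
}


def _clean(identifier: str) -> str:
    out = identifier.strip().translate(_DASHES)
    # typographic "miR-17 ~ 92" style ranges: drop internal spaces
    return "".join(out.split())


def normalize_symbol(identifier: str) -> str:
    """Canonical form for a TF or gene symbol (upper case, ASCII dashes)."""
    out = _clean(identifier).upper()
    if not out:
        raise ValueError("empty identifier")
    return out


def normalize_mirna(identifier: str) -> str:
    """Canonical form for a miRNA identifier (lower case, ASCII dashes)."""
    out = _clean(identifier).lower()
    if not out:
        raise ValueError("empty identifier")
    return out


def normalize(identifier: str, node_class: str) -> str:
    if node_class == MIRNA:
        return normalize_mirna(identifier)
    return normalize_symbol(identifier)


def parse_node_class(token: str) -> str:
    """Map a free-text class token (``TF``/``miRNA``/``gene``) to canon."""
    try:
        return _CLASS_ALIASES[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown node class token: {token!r}") from None
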