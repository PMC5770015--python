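"""The default cue-item pool: 25 items in 5 categories.

These are the guessable referents of the signalling game. Categories matter
only for documentation and for real-data bookkeeping; shortlist draws are
uniform over the pool.
"""

from __future__ import annotations

ITEM_CATEGORIES: dict[str, tuple[str, ...]] = {
    "places": ("theatre", "art gallery", "museum", "parliament", "university"),
    "actors": (
        "Robert De Niro",
        "Arnold Schwarzenegger",
        "Clint Eastwood",
        "Chuck Norris",
        "Harrison Ford",
    ),
    "entertainment": ("drama", "soap opera", "cartoon", "horror", "sci-fi"),
    "objects": ("television", "computer monitor", "microwave", "window", "iPad"),
    "abstract": ("noise", "depression", "poverty", "nausea", "violence"),
}

#: Flat, ordered item pool (category-major order, stored verbatim, case-sensitive).
DEFAULT_ITEMS: tuple[str, ...] = tuple(
    item for cat in ITEM_CATEGORIES.values() for item in cat
)


def category_of(item: str) -> str:
    """Return the category an item belongs to (raises KeyError for unknown items)."""
    for cat, members in ITEM_CATEGORIES.items():
        if item in members:
            return cat
    raise KeyError(f"unknown item: {item!r}")
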