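"""Name normalization shared by the lexicon indexes, the scorer, and the graph builder.

Entity alignment is done on lowercased names; the same rule is applied
uniformly wherever two surface strings are compared for identity.
"""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace runs.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    return _WS.sub(" ", name.strip()).casefold()
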