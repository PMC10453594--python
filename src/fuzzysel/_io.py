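"""Small shared helpers for JSON (de)serialization."""

from __future__ import annotations

import json
import os


def load_json(source):
    """Accept a path (str/PathLike), a JSON string, or an open file object."""
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            return json.load(fh)
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
        if text.lstrip().startswith("{"):
            return json.loads(text)
        with open(text) as fh:
            return json.load(fh)
    return json.load(source)
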