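"""Shared plain-text key/value configuration format.

Files are flat ``key = value`` lines; ``#`` starts a comment.  Manual
substitution overrides use dotted keys (``override.51B = G00123``), and a
synthetic-world block uses ``synth.``-prefixed keys (``synth.seed = 7``).
"""

from __future__ import annotations

from pathlib import Path

from .errors import ConfigError

__all__ = ["parse_config", "read_config"]


def parse_config(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"config line {lineno} is not 'key = value': {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"config line {lineno} has an empty key")
        if key in out:
            raise ConfigError(f"duplicate config key {key!r} (line {lineno})")
        out[key] = value
    return out


def read_config(path: str | Path) -> dict[str, str]:
    return parse_config(Path(path).read_text())
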