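"""YAML/JSON configuration loading and logging setup."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from mpcpr.errors import FormatError

log = logging.getLogger("mpcpr")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    p = Path(path)
    text = p.read_text()
    try:
        if p.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text) or {}
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from exc
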