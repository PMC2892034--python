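"""Plain-text key-value configuration files.

Format: one ``key = value`` pair per line; blank lines and lines starting
with ``#`` are ignored.  Values are parsed as int, float, or bool when they
look like one, comma-separated lists become tuples, and everything else
stays a string.
"""
from __future__ import annotations

from pathlib import Path

__all__ = ["read_config", "run_config_from_file", "simulation_config_from_file"]


def _coerce(text: str):
    text = text.strip()
    if "," in text:
        return tuple(_coerce(part) for part in text.split(","))
    low = text.lower()
    if low in ("true", "yes"):
        return True
    if low in ("false", "no"):
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def read_config(path: str | Path) -> dict:
    """Parse a key-value config file into a dictionary."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = _coerce(value)
    return out


def run_config_from_file(path: str | Path):
    """Build a pipeline RunConfig from a key-value file."""
    from .pipeline import RunConfig

    kwargs = read_config(path)
    if "characters" in kwargs and isinstance(kwargs["characters"], str):
        kwargs["characters"] = (kwargs["characters"],)
    return RunConfig(**kwargs)


def simulation_config_from_file(path: str | Path):
    """Build a SimulationConfig from a key-value file.

    Model keys: ``states`` (comma-separated labels), ``parameterization``
    and ``q`` (ER transition factor) are folded into the Mk model.
    """
    from .mk import MkModel
    from .simulate import SimulationConfig

    kwargs = read_config(path)
    states = kwargs.pop("states", ("A", "B", "C"))
    if isinstance(states, str):
        states = (states,)
    q = kwargs.pop("q", 0.5)
    kwargs["model"] = MkModel(states=tuple(str(s) for s in states), rates=float(q))
    return SimulationConfig(**kwargs)
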