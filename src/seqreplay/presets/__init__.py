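"""Packaged experiment presets (YAML)."""

from importlib import resources

__all__ = ["preset_names", "preset_path"]


def preset_names() -> list[str]:
    files = resources.files(__name__)
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def preset_path(name: str):
    path = resources.files(__name__) / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return path
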