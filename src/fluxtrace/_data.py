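"""Access to data files shipped with the package."""

from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a shipped data file."""
    return Path(str(resources.files("fluxtrace").joinpath("data", name)))
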