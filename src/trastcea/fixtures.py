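"""Paths to the bundled base-case configuration and approximate life table.

``vietnam_2020_approx.tsv`` is a synthetic Gompertz-Makeham life table
standing in for the WHO 2020 Vietnam female table (see
:mod:`trastcea.synthetic`); results computed on it approximate, but do not
reproduce, values computed on the true table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(resources.files("trastcea").joinpath("data", name))


def basecase_config_path() -> Path:
    """The published base-case parameter configuration."""
    return _data_path("basecase.ini")


def reference_lifetable_path() -> Path:
    """Approximate (synthetic) 2020 Vietnamese female life table."""
    return _data_path("vietnam_2020_approx.tsv")
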