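"""Packaged reference fixtures.

The package ships the eleven-strain reference mock community (16S copy
numbers, equal cell fractions), the published per-method mean DNA yields,
and the published per-method observed-proportion summaries (mean and SD per
taxon over eight replicates).  These are the printed summary tables of the
source study; the raw per-replicate data were never published, so anything
per-replicate built from them is a reconstruction.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .community_model import MockCommunity, load_community

__all__ = [
    "load_default_community",
    "load_yield_means",
    "load_observed_proportion_summary",
]


def _data_path(name: str):
    return resources.files("mockbench").joinpath("data", name)


def load_default_community() -> MockCommunity:
    """The packaged eleven-strain community with equal cell fractions."""
    with resources.as_file(_data_path("community_default.tsv")) as path:
        return load_community(path)


def load_yield_means() -> pd.DataFrame:
    """Published mean DNA concentrations (µg/ml), wide: sample x method."""
    with resources.as_file(_data_path("yield_means_default.tsv")) as path:
        long = pd.read_csv(path, sep="\t", dtype={"method": str})
    return long.pivot(index="sample", columns="method", values="mean_concentration")


def load_observed_proportion_summary() -> pd.DataFrame:
    """Published observed proportions: taxon, method, mean_pct, sd_pct."""
    with resources.as_file(_data_path("observed_proportions_default.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"method": str})
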