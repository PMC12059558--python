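"""End-to-end convenience wrappers: cores and tables in, posterior out."""

from __future__ import annotations

import pandas as pd

from .community import (
    CommunityMatrix,
    TaxaSelection,
    hellinger_transform,
    relative_abundance,
    select_dominant_taxa,
)
from .dendro import assemble_growth_table
from .model import ModelData, PosteriorSamples, build_design, fit_mcmc
from .synthetic import SyntheticStudy


def study_growth_table_via_dendro(study: SyntheticStudy) -> pd.DataFrame:
    """Rebuild the growth table from the study's ring series and metadata.

    Exercises the same code path field data would take: core averaging,
    historical dbh reconstruction anchored on the measured diameter, BAI and
    per-tree standardization.
    """
    g = study.growth_table
    last = g.sort_values("year").groupby("tree_id").tail(1).set_index("tree_id")
    meta = pd.DataFrame(
        {
            "dbh_final": study.dbh_final,
            "age_final": last["age"].astype(float),
            "species": last["species"],
            "location": last["location"],
            "nmin": last["nmin"],
        }
    )
    climate = (
        g[["location", "year", "min_may_t"]].drop_duplicates(["location", "year"])
    )
    return assemble_growth_table(
        study.ring_series,
        meta,
        climate,
        start_year=int(g.year.min()),
        end_year=int(g.year.max()),
    )


def prepare_community(
    community: CommunityMatrix, k: int = 7, n_components: int = 3
) -> tuple[CommunityMatrix, TaxaSelection]:
    """Counts or relative abundances -> Hellinger matrix + dominant taxa."""
    if community.state == "counts":
        community = relative_abundance(community)
    hel = hellinger_transform(community)
    return hel, select_dominant_taxa(hel, k=k, n_components=n_components)


def fit_growth_model(
    growth: pd.DataFrame,
    community: CommunityMatrix,
    k: int = 7,
    **fit_kwargs,
) -> tuple[ModelData, TaxaSelection, PosteriorSamples]:
    """Full pipeline from a growth table and an abundance matrix to draws."""
    hel, sel = prepare_community(community, k=k)
    data = build_design(growth, hel, sel)
    post = fit_mcmc(data, **fit_kwargs)
    return data, sel, post
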