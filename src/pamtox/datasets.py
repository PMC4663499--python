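"""Loaders for the reference tables shipped with the package.

Four small CSV fixtures accompany the code: physicochemical properties of the
ten PSII herbicides, the published single-compound inhibition endpoints
(IC10/IC50 with 95 % CIs per exposure duration), the published mixture
endpoints on the TU_sum scale, guideline ETV sets with their reported
protectiveness flags, and a literature compilation of cross-species toxicity
(reference material only — no computation consumes it).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mixtures import ToxicUnitTable

__all__ = [
    "herbicide_properties",
    "inhibition_endpoints",
    "mixture_endpoints",
    "guideline_etvs",
    "cross_species_toxicity",
    "toxic_unit_table",
    "guideline_icx",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("pamtox.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, **kwargs)


def herbicide_properties() -> pd.DataFrame:
    """Chemical class, log Kow, water solubility and CAS number per herbicide."""
    return _read("herbicide_properties.csv")


def inhibition_endpoints() -> pd.DataFrame:
    """Published IC10/IC50 (µg/l, 95 % CI) per herbicide and duration.

    ``rep_reported`` is the published relative potency as printed; for a few
    rows it differs from the ratio of the rounded printed IC50s (it was
    evidently computed from unrounded fits), so recomputed ReP values should
    be compared against the self-consistent rows only.
    """
    return _read("inhibition_endpoints.csv")


def mixture_endpoints() -> pd.DataFrame:
    """Published mixture IC10/IC50 on the TU_sum scale with letter groupings."""
    return _read("mixture_endpoints.csv")


def guideline_etvs() -> pd.DataFrame:
    """Ecotoxicity threshold values (long format) with reported flags.

    One row per (herbicide, source, protection level); ``etv_ugL`` is NaN
    where no guideline exists. ``reported_nonprotective`` reproduces the
    published protectiveness marking verbatim (1 = marked non-protective);
    one tebuthiuron cell is internally inconsistent with the published
    decision rule — see the methods note.
    """
    df = _read("guideline_etvs.csv")
    df["reported_nonprotective"] = df["reported_nonprotective"].astype("boolean")
    return df


def cross_species_toxicity() -> pd.DataFrame:
    """Literature cross-species toxicity compilation (reference only)."""
    return _read("cross_species_toxicity.csv")


def toxic_unit_table(duration_h: float = 24.0) -> ToxicUnitTable:
    """Toxic-Unit basis from the shipped endpoints: 1 TU = IC50 at ``duration_h``."""
    ep = inhibition_endpoints()
    sel = ep[ep["duration_h"] == duration_h]
    if sel.empty:
        raise ValueError(f"no endpoints at {duration_h} h")
    return ToxicUnitTable(
        entries=dict(zip(sel["herbicide"], sel["ic50"].astype(float))),
        duration_h=duration_h,
    )


def guideline_icx(level: int = 10) -> dict[str, float]:
    """ICx values used for guideline screening, one per herbicide.

    For the slow-acting compounds the longest measured exposure (48 h) is
    used, matching how the published threshold comparison was made; the rest
    use the 24 h endpoint.
    """
    ep = inhibition_endpoints()
    col = f"ic{level}"
    if col not in ep.columns:
        raise ValueError(f"no IC{level} column in the endpoint table")
    ep = ep.sort_values("duration_h").groupby("herbicide").last()
    return ep[col].astype(float).to_dict()
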