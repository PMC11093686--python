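"""Packaged homocysteine -> PCOS instrument table and cohort metadata.

The bundled table holds the 14 homocysteine instruments (selected at
genome-wide significance from a meta-GWAS of 44,147 Europeans, LD-pruned and
screened for pleiotropy) together with their per-allele associations with
polycystic ovary syndrome in three European case-control GWAS: FinnGen
release 7, Day et al., and Tyrmi et al.  Three CBS/CPS1-region variants
(rs7422339, rs234709, rs2851391) are absent from FinnGen and carried as NA,
so the FinnGen instrument set has 11 members.

Exposure betas are in SD units of plasma homocysteine; outcome betas are
log-odds of PCOS.  All studies report effects on the same coded allele, so
harmonization of this table involves no sign flips.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import InstrumentSet, VariantAssociation, harmonize

__all__ = [
    "STUDIES",
    "STUDY_LABELS",
    "N_EXPOSURE",
    "OUTCOME_COHORTS",
    "FINNGEN_MISSING",
    "load_instrument_table",
    "exposure_associations",
    "outcome_associations",
    "study_instrument_set",
]

#: machine keys and display labels of the three outcome GWAS
STUDIES = ("finngen", "day", "tyrmi")
STUDY_LABELS = {"finngen": "FinnGen", "day": "Day et al.", "tyrmi": "Tyrmi et al."}

#: exposure meta-GWAS sample size (plasma homocysteine, European cohorts)
N_EXPOSURE = 44_147

#: (cases, controls) per outcome GWAS
OUTCOME_COHORTS = {
    "finngen": (994, 165_817),
    "day": (4_138, 20_129),
    "tyrmi": (3_609, 229_788),
}

#: instruments with no FinnGen association and no proxy at r^2 > 0.8
FINNGEN_MISSING = ("rs7422339", "rs234709", "rs2851391")


def load_instrument_table() -> pd.DataFrame:
    """The packaged instrument table as a DataFrame (NA where unavailable)."""
    ref = resources.files("hcymr.data") / "hcy_pcos_instruments.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def exposure_associations() -> list[VariantAssociation]:
    """The 14 variant-homocysteine associations (SD units per allele)."""
    df = load_instrument_table()
    return [
        VariantAssociation(
            variant_id=row.variant_id,
            effect_allele=row.effect_allele,
            beta=row.beta_exposure,
            se=row.se_exposure,
            p_value=row.p_exposure,
            chromosome=str(row.chromosome),
            nearby_gene=row.nearby_gene,
        )
        for row in df.itertuples(index=False)
    ]


def outcome_associations(study: str) -> list[VariantAssociation]:
    """Variant-PCOS associations (log-odds per allele) for one outcome GWAS."""
    if study not in STUDIES:
        raise KeyError(f"unknown study {study!r}; expected one of {STUDIES}")
    df = load_instrument_table()
    out: list[VariantAssociation] = []
    for row in df.itertuples(index=False):
        beta = getattr(row, f"beta_{study}")
        se = getattr(row, f"se_{study}")
        if pd.isna(beta) or pd.isna(se):
            continue
        pval = getattr(row, f"p_{study}")
        out.append(VariantAssociation(
            variant_id=row.variant_id,
            effect_allele=row.effect_allele,
            beta=float(beta),
            se=float(se),
            p_value=None if pd.isna(pval) else float(pval),
            chromosome=str(row.chromosome),
            nearby_gene=row.nearby_gene,
        ))
    return out


def study_instrument_set(study: str) -> InstrumentSet:
    """Harmonized instruments for one outcome GWAS, with cohort sizes attached."""
    cases, controls = OUTCOME_COHORTS[study]
    iset, _ = harmonize(
        exposure_associations(),
        outcome_associations(study),
        label=STUDY_LABELS[study],
        n_exposure=N_EXPOSURE,
        n_outcome_cases=cases,
        n_outcome_controls=controls,
    )
    return iset
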