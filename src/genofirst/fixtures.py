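"""Packaged fixture tables.

The published study deposited no raw data; its four summary tables (variant
panel, personal cancer cross-tab, breast-cancer cases, other cancers) are
shipped verbatim as TSV and loaded here.  ``validate_fixtures`` asserts the
structural invariants (row counts, per-gene case sums) so accidental edits
fail loudly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Per-gene case sums of the variant panel table (sum 108; the counseled
# cohort has 109 participants - a known discrepancy of the source tables,
# transcribed verbatim and documented, not reconciled).
EXPECTED_GENE_CASES = {"BRCA1": 59, "BRCA2": 25, "CHEK2": 15, "ATM": 6, "NBN": 2, "NF1": 1}

N_COUNSELED = 109


def _read(name: str, **kw) -> pd.DataFrame:
    ref = resources.files("genofirst.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", **kw)


def load_table1() -> pd.DataFrame:
    """16 P/LP panel variants with per-variant case counts and ClinVar class."""
    return _read("table1.tsv")


def load_table2() -> pd.DataFrame:
    """Personal cancer diagnoses cross-tabulated by location and onset band."""
    return _read("table2.tsv")


def load_table4() -> pd.DataFrame:
    """The 16 prevalent/incident breast-cancer cases among participants."""
    return _read("table4.tsv", dtype={"id": int, "age_at_dx": int})


def load_table5() -> pd.DataFrame:
    """The 7 non-breast cancers among participants."""
    return _read("table5.tsv", dtype={"id": int, "age_at_dx": int})


def load_panel_loci() -> pd.DataFrame:
    """Synthetic GRCh37 join-key loci for the panel variants."""
    return _read("panel_loci_synthetic.tsv", dtype={"chrom": str})


def load_clinvar() -> pd.DataFrame:
    """Synthetic mini ClinVar-style assertion table for the panel."""
    return _read("clinvar_synthetic.tsv", dtype={"chrom": str})


def load_rules() -> pd.DataFrame:
    """Versioned testing-eligibility rule table."""
    return _read("rules.tsv", dtype={"max_onset_age": "Float64"})


def validate_fixtures() -> None:
    t1, t2, t4, t5 = load_table1(), load_table2(), load_table4(), load_table5()
    gene_sums = t1.groupby("gene")["cases"].sum().to_dict()
    if gene_sums != EXPECTED_GENE_CASES:
        raise ValueError(f"table1 per-gene case sums changed: {gene_sums}")
    bands = ["lt40", "age40_49", "age50_59", "gt59"]
    if int(t2[bands].to_numpy().sum()) != 16:
        raise ValueError("table2 cells must sum to 16")
    if len(t4) != 16:
        raise ValueError("table4 must have 16 rows")
    if len(t5) != 7:
        raise ValueError("table5 must have 7 rows")
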