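"""Bundled reference tables.

Two small published tables ship with the package:

* the 40 signed LCB orders of diatom plastomes (42 blocks each, one
  inverted-repeat copy removed), the substrate for gene-order grouping and
  pairwise inversion distances;
* the M7/M8 site-model log-likelihoods for the two fast-evolving genes
  (rps5, atpI), the inputs to the likelihood-ratio-test arithmetic.
"""
from importlib.resources import files

import pandas as pd


def lcb_orders_path() -> str:
    """Path to the bundled signed-LCB-order TSV (40 diatom plastomes)."""
    return str(files("plastorate") / "data" / "table2_lcb_orders.tsv")


def site_model_lnl() -> pd.DataFrame:
    """M7/M8 log-likelihoods for rps5 and atpI (columns gene, model, lnL, df)."""
    return pd.read_csv(str(files("plastorate") / "data" / "table1_site_model_lnL.tsv"), sep="\t")
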