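"""Small bundled example tables used by worked-example tests and docs."""

from importlib import resources

import pandas as pd


def load_pathway_dmp_table() -> pd.DataFrame:
    """The 38-row CREB/CaMKII-pathway per-DMP summary table.

    Columns: ``gene, probe_id, sign_at_work`` (``Hypo``/``Hyper`` during the
    working period), ``ewas_p`` (SWD-group vacation-effect p),
    ``anova_work_p`` (work-period group comparison), and ``spearman_r`` /
    ``spearman_p`` (correlation of the methylation change with the
    symptom-change recovery score).
    """
    with resources.files(__package__).joinpath("creb_camkii_dmps.tsv").open() as handle:
        return pd.read_csv(handle, sep="\t")
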