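"""Small packaged demonstration datasets.

The repurposing demo is a hand-built synthetic fixture: the drug names and
DrugBank/TTD codes are real, publicly documented identifiers of approved
drugs, but the gene-target assignments are synthetic placeholders (symbols
``SGT*`` for screen-target genes, ``INT*`` for first-shell interactors).  It
is sized so that 14 approved drugs target genes in both lists within the
DB-dialect table and 6 approved drugs appear, by name, in both databases.
"""

from __future__ import annotations

from importlib import resources

from .drug_mining import DrugTargetRecord, load_drug_table
from .synthetic_data import read_gene_list


def _data_path(name: str):
    return resources.files("oxscreen").joinpath("data", name)


def load_repurposing_demo() -> dict:
    """Load the synthetic drug-repurposing demo fixture.

    Returns a dict with keys ``targets`` and ``interactors`` (gene lists),
    ``db_records`` and ``ttd_records`` (normalized drug-target records).
    """
    with resources.as_file(_data_path("repurposing_demo_db.tsv")) as p:
        db_records: list[DrugTargetRecord] = load_drug_table(p, dialect="DB")
    with resources.as_file(_data_path("repurposing_demo_ttd.tsv")) as p:
        ttd_records = load_drug_table(p, dialect="TTD")
    with resources.as_file(_data_path("repurposing_demo_targets.txt")) as p:
        targets = read_gene_list(p)
    with resources.as_file(_data_path("repurposing_demo_interactors.txt")) as p:
        interactors = read_gene_list(p)
    return {
        "targets": targets,
        "interactors": interactors,
        "db_records": db_records,
        "ttd_records": ttd_records,
    }
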