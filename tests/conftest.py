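import numpy as np
import pandas as pd
import pytest

from gclfq.digestion import DigestionParams, GeneModel, ProteinIsoform, build_gene_models
from gclfq.quantify import quantify
from gclfq.simulate import SimulationConfig, generate_proteome, simulate_peptide_measurements


@pytest.fixture(scope="session")
def default_bundle():
    """One simulated study under the default generator conditions
    (14 subjects, 900 genes, >6 decades of baseline abundance, dropout)."""
    config = SimulationConfig(seed=20260101)
    isoforms = generate_proteome(config)
    table, design, truth = simulate_peptide_measurements(config, isoforms)
    return config, isoforms, table, design, truth


@pytest.fixture(scope="session")
def default_quant(default_bundle):
    config, isoforms, table, design, truth = default_bundle
    genes = build_gene_models(isoforms, config.digestion)
    quant, report = quantify(table, genes, config.digestion, design)
    return quant, report, truth


@pytest.fixture()
def toy_genes():
    """Two single-isoform genes with disjoint digest peptides plus a gene
    sharing a peptide with the first (for assignment-policy tests)."""
    params = DigestionParams(min_peptide_length=3, max_peptide_length=30)
    isoforms = [
        ProteinIsoform("A.1", "GENEA", "1", "MKVVVK" + "AAPLLK" + "TTTWR"),
        ProteinIsoform("B.1", "GENEB", "2", "MDDDDK" + "GGGFFK" + "HHHYR"),
        # shares the AAPLLK tryptic peptide with GENEA
        ProteinIsoform("C.1", "GENEC", "3", "MEEEEK" + "AAPLLK" + "WWWIR"),
    ]
    return build_gene_models(isoforms, params), params


def paired_design(n_subjects: int) -> pd.DataFrame:
    from gclfq.quantify import TIMEPOINTS

    rows = []
    for i in range(n_subjects):
        subj = f"S{i + 1:02d}"
        for tp, short in zip(TIMEPOINTS, ("T0", "T1", "T2")):
            rows.append({"sample_id": f"{subj}_{short}", "subject_id": subj, "timepoint": tp})
    return pd.DataFrame(rows)


@pytest.fixture()
def make_log_ifot():
    """Factory: build a (log_ifot, design) pair from per-timepoint gene
    value dictionaries, e.g. {'g1': {'T0': [..per subject..], 'T1': [...]}}."""

    def _make(values: dict[str, dict[str, list[float]]]):
        n_subjects = len(next(iter(next(iter(values.values())).values())))
        design = paired_design(n_subjects)
        cols = list(design["sample_id"])
        data = {}
        for gene, per_tp in values.items():
            row = []
            for i in range(n_subjects):
                for short in ("T0", "T1", "T2"):
                    tp_vals = per_tp.get(short)
                    row.append(np.nan if tp_vals is None else tp_vals[i])
            data[gene] = row
        # design order is subject-major, timepoint-minor; match it
        log_ifot = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        return log_ifot, design

    return _make
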