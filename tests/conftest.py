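import numpy as np
import pytest

from extractbench.model import (
    AcquisitionMode,
    MeasurementTable,
    Metabolite,
    MetabolitePanel,
    SampleKey,
)
from extractbench.synthetic import SyntheticConfig, generate

#: Compact panel spec reused across tests: 3 classes, 12 metabolites.
SMALL_PANEL_SPEC = {
    "amino acids": (5, "LC", "AA"),
    "biogenic amines": (3, "LC", "BAM"),
    "triacylglycerols": (4, "FIA", "TG"),
}


def make_panel(names_classes_modes):
    return MetabolitePanel(
        tuple(Metabolite(n, c, AcquisitionMode(m)) for n, c, m in names_classes_modes)
    )


def build_table(panel, cells):
    """Assemble a MeasurementTable from explicit cells.

    ``cells`` maps (organism, tissue, protocol, replicate) → per-metabolite
    (concentration, status) pairs keyed by metabolite name; unlisted
    metabolites are missing.
    """
    samples = [SampleKey(*k) for k in cells]
    conc = np.full((len(samples), len(panel)), np.nan)
    stat = np.full((len(samples), len(panel)), "missing", dtype=object)
    col = {n: j for j, n in enumerate(panel.names)}
    for i, key in enumerate(cells):
        for met, (c, s) in cells[key].items():
            conc[i, col[met]] = np.nan if c is None else c
            stat[i, col[met]] = s
    return MeasurementTable.from_arrays(panel, samples, conc, stat)


def triplicate_table(statuses, concentrations=(5.0, 6.0, 7.0)):
    """One metabolite, one (matrix, protocol) triplicate group."""
    panel = make_panel([("M1", "amino acids", "LC")])
    cells = {}
    for r, (s, c) in enumerate(zip(statuses, concentrations), start=1):
        value = None if s == "missing" else c
        cells[("mouse", "kidney", "P1", r)] = {"M1": (value, s)}
    return build_table(panel, cells)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        panel_spec=SMALL_PANEL_SPEC,
        matrices=(("mouse", "kidney"), ("zebrafish", "liver")),
        protocols=("P1", "P2", "P3"),
        replicates=3,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_table(small_config):
    table, _ = generate(small_config)
    return table


@pytest.fixture(scope="session")
def small_truth(small_config):
    _, truth = generate(small_config)
    return truth
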