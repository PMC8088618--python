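import numpy as np
import pytest

from dtifuse.interactome import LabeledPairSet
from dtifuse.synthetic import SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """One modest synthetic benchmark shared by read-only tests."""
    cfg = SyntheticConfig(n_proteins=40, n_compounds=40, n_pairs=250, seed=7)
    return generate_benchmark(cfg)


@pytest.fixture()
def toy_pairs():
    records = [
        (f"P{i}", f"C{j}", (i + j) % 2)
        for i in range(5)
        for j in range(4)
    ]
    return LabeledPairSet.from_records(records)


def write_link_table(path, rows, channel="experimental",
                     ids=("item_a", "item_b")):
    with open(path, "w") as fh:
        fh.write(f"{ids[0]}\t{ids[1]}\t{channel}\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s}\n")
    return path


@pytest.fixture()
def link_table_writer(tmp_path):
    def _write(rows, channel="experimental", name="links.txt"):
        return write_link_table(tmp_path / name, rows, channel)

    return _write
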