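import numpy as np
import pytest

from xpoo import (FEMALE, MALE, MISSING, SimSpec, SnpInfo, TriadDataset,
                  TriadRecord, simulate_triads)


def make_triad(triad_id, sex, mother, father, child):
    return TriadRecord(triad_id, sex,
                       np.asarray(mother, dtype=np.int8),
                       np.asarray(father, dtype=np.int8),
                       np.asarray(child, dtype=np.int8))


def make_dataset(triads, n_snps=1):
    snps = [SnpInfo(f"rs{j + 1}", 1000 * (j + 1), "A", "B") for j in range(n_snps)]
    return TriadDataset(snps, triads)


@pytest.fixture
def clean_dataset():
    """12 fully observed, Mendelian-consistent triads at one SNP."""
    triads = [
        make_triad("t1", FEMALE, [1], [0], [1]),
        make_triad("t2", FEMALE, [1], [1], [1]),
        make_triad("t3", FEMALE, [2], [1], [2]),
        make_triad("t4", FEMALE, [0], [0], [0]),
        make_triad("t5", FEMALE, [1], [1], [2]),
        make_triad("t6", FEMALE, [0], [1], [1]),
        make_triad("t7", MALE, [1], [0], [1]),
        make_triad("t8", MALE, [1], [1], [0]),
        make_triad("t9", MALE, [0], [0], [0]),
        make_triad("t10", MALE, [2], [1], [1]),
        make_triad("t11", MALE, [1], [0], [0]),
        make_triad("t12", FEMALE, [1], [0], [0]),
    ]
    return make_dataset(triads)


@pytest.fixture
def null_sim_600():
    """600 triads simulated with no effect anywhere (seeded)."""
    return simulate_triads(SimSpec(maf=0.2, rrm=1.0, rrf=1.0, n_triads=600, seed=42))


@pytest.fixture
def effect_sim_2000():
    """2000 triads at MAF 0.2 with RRm = 2, RRf = 1 under X-inactivation."""
    return simulate_triads(SimSpec(maf=0.2, rrm=2.0, rrf=1.0,
                                   true_model="x_inactivation",
                                   n_triads=2000, seed=7))


def write_ped_map(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "test.ped"
    map_ = tmp_path / "test.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    map_.write_text("\n".join(map_lines) + "\n")
    return ped, map_
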