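"""frequency_analysis: contact counting, frequencies and histograms."""

import logging

import numpy as np
import pytest

from pistacks import (Context, InteractionType, Scope, count_contacts,
                      detect_all, geometry_histograms, relative_frequencies)
from pistacks.detect import InteractionRecord, PartnerRef
from pistacks.frequency import sidechain_coords
from pistacks.geometry import PairGeometry

from conftest import make_residue, make_structure


def _rec(itype, d=3.8, alpha=10.0, beta=0.0, context=Context.INTRA):
    geom = PairGeometry(d=d, atom_1="CG", atom_2="X", alpha=alpha,
                        lateral_offset=1.0, ring_used=6, beta=beta)
    return InteractionRecord(
        itype=InteractionType(itype),
        partner1=PartnerRef(("A", 1, ""), "PHE", "aromatic_ring", 6),
        partner2=PartnerRef(("A", 2, ""), "LYS", "cation"),
        geometry=geom, context=context)


def test_contacts_two_ala_pair():
    r1 = make_residue("ALA", {"CB": ("C", (0, 0, 0)), "CA": ("C", (0, 1.5, 0))},
                      seq=1)
    r2 = make_residue("ALA", {"CB": ("C", (4.0, 0, 0))}, seq=2)
    assert count_contacts(make_structure([r1, r2])) == 1
    r2far = make_residue("ALA", {"CB": ("C", (5.5, 0, 0))}, seq=2)
    assert count_contacts(make_structure([r1, r2far])) == 0


def test_gly_has_no_side_chain():
    gly = make_residue("GLY", {"CA": ("C", (0, 0, 0)), "N": ("N", (1.4, 0, 0))},
                       seq=1)
    ala = make_residue("ALA", {"CB": ("C", (1.0, 0, 0))}, seq=2)
    assert sidechain_coords(gly).shape == (0, 3)
    assert count_contacts(make_structure([gly, ala])) == 0


def test_contacts_bruteforce_oracle():
    rng = np.random.default_rng(13)
    residues = []
    for i in range(30):
        n = rng.integers(1, 4)
        atoms = {f"C{k}": ("C", rng.uniform(0, 18, 3)) for k in range(n)}
        atoms[f"CB"] = ("C", rng.uniform(0, 18, 3))
        residues.append(make_residue("LEU", atoms, seq=i + 1))
    s = make_structure(residues)
    expected = 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            c1 = sidechain_coords(residues[i])
            c2 = sidechain_coords(residues[j])
            dmin = min(np.linalg.norm(a - b) for a in c1 for b in c2)
            expected += dmin <= 5.0
    assert count_contacts(s) == expected


def test_contacts_interface_scope():
    a = make_residue("ALA", {"CB": ("C", (0, 0, 0))}, chain="A", seq=1)
    a2 = make_residue("ALA", {"CB": ("C", (2.0, 0, 0))}, chain="A", seq=2)
    b = make_residue("ALA", {"CB": ("C", (4.0, 0, 0))}, chain="B", seq=1)
    s = make_structure([a, a2, b])
    assert count_contacts(s) == 3                      # all three pairs
    s.scope = Scope.interface({"A"}, {"B"})
    assert count_contacts(s) == 2                      # only cross-chain pairs


def test_nucleotide_side_chain_is_the_base(tmp_path):
    from pistacks import generate_stair_fixture, parse_pdb
    pdb, _, _ = generate_stair_fixture(1, seed=0)
    p = tmp_path / "l.pdb"
    p.write_text(pdb)
    s = parse_pdb(p)
    dg = next(r for r in s.residues() if r.resname == "DG")
    # every atom of the synthetic guanine is a base atom
    assert sidechain_coords(dg).shape[0] == len(dg.atoms)


def test_relative_frequency_arithmetic():
    table = relative_frequencies({"s1": ([], 50)})
    assert (table.frequencies.loc["s1"] == 0).all()

    recs = [_rec("pi_pi"), _rec("pi_pi")]
    table = relative_frequencies({"s1": (recs, 100)})
    assert table.frequencies.loc["s1", "pi_pi"] == pytest.approx(2.0)

    batch = {
        "s1": ([_rec("pi_pi")] * 2, 100),
        "s2": ([_rec("pi_pi")] * 3 + [_rec("cation_pi")], 50),
        "s3": ([], 25),
    }
    table = relative_frequencies(batch)
    pipi = np.array([2.0, 6.0, 0.0])
    assert table.mean["pi_pi"] == pytest.approx(pipi.mean())
    assert table.std["pi_pi"] == pytest.approx(pipi.std(ddof=0))
    assert table.mean["cation_pi"] == pytest.approx(np.mean([0, 2.0, 0]))


def test_relative_frequency_skips_zero_contacts(caplog):
    with caplog.at_level(logging.WARNING, logger="pistacks.frequency"):
        table = relative_frequencies({"bad": ([_rec("pi_pi")], 0),
                                      "ok": ([], 10)})
    assert list(table.frequencies.index) == ["ok"]
    with pytest.raises(ValueError):
        relative_frequencies({"bad": ([], 0)})


def test_base_base_excluded_from_frequencies():
    recs = [_rec("pi_pi"), _rec("pi_pi", context=Context.BASE_BASE)]
    table = relative_frequencies({"s": (recs, 100)})
    assert table.per_structure.loc["s", "pi_pi"] == 1


def test_duplicating_the_batch_preserves_mean_and_std():
    batch = {"s1": ([_rec("pi_pi")] * 2, 100), "s2": ([_rec("pi_pi")], 20)}
    doubled = dict(batch)
    doubled.update({f"{k}_copy": v for k, v in batch.items()})
    t1 = relative_frequencies(batch)
    t2 = relative_frequencies(doubled)
    assert t1.mean["pi_pi"] == pytest.approx(t2.mean["pi_pi"])
    assert t1.std["pi_pi"] == pytest.approx(t2.std["pi_pi"])


def test_histogram_all_alpha_zero_in_first_bin():
    recs = [_rec("pi_pi", alpha=0.0) for _ in range(5)]
    hist = geometry_histograms(recs, "one_minus_cos_alpha", bins=10,
                               value_range=(0.0, 1.0))
    dens = hist.densities["pi_pi"]
    assert dens[0] == pytest.approx(1.0)
    assert dens[1:].sum() == pytest.approx(0.0)
    assert dens.sum() == pytest.approx(1.0)


def test_histogram_matches_direct_tabulation():
    alphas = np.linspace(0.0, 80.0, 17)
    recs = [_rec("pi_pi", alpha=a) for a in alphas]
    edges = np.linspace(0.0, 1.0, 11)
    hist = geometry_histograms(recs, "one_minus_cos_alpha", bins=edges)
    values = 1.0 - np.cos(np.radians(alphas))
    counts, _ = np.histogram(values, bins=edges)
    assert np.array_equal(hist.counts["pi_pi"], counts)
    assert hist.densities["pi_pi"] == pytest.approx(counts / counts.sum())


def test_histogram_mode_and_d_variable():
    recs = [_rec("pi_pi", d=3.7)] * 3 + [_rec("pi_pi", d=4.9)]
    hist = geometry_histograms(recs, "d", bins=np.arange(3.0, 5.2, 0.2))
    assert hist.mode("pi_pi") == pytest.approx(3.7, abs=0.1)


def test_beta_histogram_excludes_undefined_records():
    lys = [_rec("cation_pi", beta=None)]
    with pytest.raises(ValueError):
        geometry_histograms(lys, "one_minus_cos_beta")
    mixed = lys + [_rec("pi_pi", beta=30.0)]
    hist = geometry_histograms(mixed, "one_minus_cos_beta", bins=5)
    assert set(hist.densities) == {"pi_pi"}


def test_unknown_variable_raises():
    with pytest.raises(ValueError):
        geometry_histograms([_rec("pi_pi")], "gamma")
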