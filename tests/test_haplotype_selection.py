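"""Haplotype classes, mixed-model letter display, selection efficiency."""

import numpy as np
import pandas as pd
import pytest

from sproutval._tukey import compact_letter_display
from sproutval.haplotype_selection import (
    build_haplotypes,
    haplotype_mixed_model,
    selection_efficiency,
)

TOL = {"m1": "G", "m2": "T", "m3": "C"}


def _calls(cells: dict[str, list[str]]):
    n = len(next(iter(cells.values())))
    return pd.DataFrame(cells, index=[f"G{i:03d}" for i in range(n)]).astype("string")


def test_two_marker_class_bound_and_partition():
    calls = _calls({
        "m1": ["GG"] * 4 + ["AA"] * 4 + ["GG", "NA"],
        "m2": ["TT", "TT", "CC", "CC"] * 2 + ["GT", "TT"],
    })
    classes = build_haplotypes(calls, ["m1", "m2"], TOL)
    assert len(classes) <= 4
    # genotypes with missing or het calls at any marker are excluded
    assert sum(c.n for c in classes) == 8


def test_absent_combination_and_rare_flag():
    # 3-marker panel with one combination absent and one singleton class
    combos = (["GG|TT|CC"] * 4 + ["GG|TT|AA"] * 3 + ["GG|CC|CC"] * 3
              + ["GG|CC|AA"] * 3 + ["AA|TT|CC"] * 3 + ["AA|TT|AA"] * 3
              + ["AA|CC|CC"] * 1)  # AA|CC|AA never observed; AA|CC|CC rare
    split = [c.split("|") for c in combos]
    calls = _calls({"m1": [s[0] for s in split],
                    "m2": [s[1] for s in split],
                    "m3": [s[2] for s in split]})
    classes = build_haplotypes(calls, ["m1", "m2", "m3"], {**TOL, "m3": "C"})
    assert len(classes) == 7          # 7 of 8 possible combinations observed
    rare = [c for c in classes if c.rare]
    assert len(rare) == 1 and rare[0].n == 1


def _blups_long(values_by_geno: dict[str, float], n_env=4, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, v in values_by_geno.items():
        for j in range(n_env):
            rows.append({"genotype_id": g, "environment_id": f"E{j + 1}",
                         "blup": v + rng.normal(0, sd)})
    return pd.DataFrame(rows)


def test_separated_classes_get_distinct_letters():
    """Planted class means 0.25 vs 0.45 (n=40 each, SD 0.05): power ~ 1."""
    rng = np.random.default_rng(1)
    calls = _calls({"m1": ["GG"] * 40 + ["AA"] * 40})
    vals = {f"G{i:03d}": (0.25 if i < 40 else 0.45) + rng.normal(0, 0.05)
            for i in range(80)}
    classes = build_haplotypes(calls, ["m1"], TOL)
    table = haplotype_mixed_model(_blups_long(vals), classes)
    letters = table.set_index("haplotype")["letter"]
    assert letters["G(tol)"] != letters["A(sus)"]
    assert table.iloc[0]["haplotype"] == "G(tol)"  # lowest mean listed first


def test_null_classes_share_letter_most_of_the_time():
    """Tukey-Kramer holds family-wise error near 0.05 under the null."""
    all_one_letter = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        calls = _calls({"m1": ["GG"] * 20 + ["AA"] * 20,
                        "m2": (["TT"] * 10 + ["CC"] * 10) * 2})
        vals = {f"G{i:03d}": 0.35 + rng.normal(0, 0.1) for i in range(40)}
        classes = build_haplotypes(calls, ["m1", "m2"], TOL)
        table = haplotype_mixed_model(_blups_long(vals), classes)
        if table[~table["rare"]]["letter"].nunique() == 1:
            all_one_letter += 1
    assert all_one_letter >= 0.90 * n_seeds


def test_identical_responses_single_letter():
    calls = _calls({"m1": ["GG"] * 5 + ["AA"] * 5})
    vals = {f"G{i:03d}": 0.4 for i in range(10)}
    classes = build_haplotypes(calls, ["m1"], TOL)
    table = haplotype_mixed_model(_blups_long(vals), classes)
    assert table["lsmean_gi"].nunique() == 1
    assert table["letter"].nunique() == 1


def test_rare_class_excluded_from_letters():
    rng = np.random.default_rng(3)
    calls = _calls({"m1": ["GG"] * 10 + ["AA"] * 10 + ["GG"],
                    "m2": ["TT"] * 10 + ["TT"] * 10 + ["CC"]})
    vals = {f"G{i:03d}": 0.3 + rng.normal(0, 0.05) for i in range(21)}
    classes = build_haplotypes(calls, ["m1", "m2"], TOL)
    table = haplotype_mixed_model(_blups_long(vals), classes)
    rare_rows = table[table["rare"]]
    assert len(rare_rows) == 1
    assert (rare_rows["letter"] == "").all()


def test_all_tolerant_class_most_dormant_noise_free():
    """With non-positive planted effects the all-tolerant class has the
    lowest mean on noise-free data."""
    calls = _calls({"m1": ["GG"] * 5 + ["GG"] * 5 + ["AA"] * 5 + ["AA"] * 5,
                    "m2": ["TT"] * 5 + ["CC"] * 5 + ["TT"] * 5 + ["CC"] * 5})
    eff = {"GG": -0.10, "AA": 0.0}
    eff2 = {"TT": -0.05, "CC": 0.0}
    vals = {}
    for i in range(20):
        g = f"G{i:03d}"
        vals[g] = 0.45 + eff[calls.loc[g, "m1"]] + eff2[calls.loc[g, "m2"]]
    classes = build_haplotypes(calls, ["m1", "m2"], TOL)
    table = haplotype_mixed_model(_blups_long(vals), classes)
    assert table.iloc[0]["haplotype"] == "G(tol)/T(tol)"
    assert table.iloc[-1]["haplotype"] == "A(sus)/C(sus)"


def test_letter_display_chain_uses_three_letters():
    """If A~B and B~C but A!=C, the display needs a letter for each overlap."""
    p = np.ones((3, 3))
    p[0, 2] = p[2, 0] = 0.001  # only the extremes differ
    letters = compact_letter_display(p, np.array([0, 1, 2]), alpha=0.05)
    assert letters[0] != letters[2]
    assert set(letters[1]) & set(letters[0])
    assert set(letters[1]) & set(letters[2])


def test_top20_size_and_identical_sets():
    rng = np.random.default_rng(4)
    genos = [f"G{i:03d}" for i in range(200)]
    blups = pd.DataFrame({"genotype_id": genos,
                          "blup": rng.normal(0.35, 0.15, 200)})
    members = genos[:30]
    cmp_ = selection_efficiency(members, members, blups)
    assert cmp_.top20_size == 40
    assert cmp_.n_haplotype_in_top20 == cmp_.n_marker_in_top20
    assert cmp_.t_test_p == pytest.approx(1.0)


def test_refining_haplotype_selects_more_dormant_genotypes():
    """A two-marker haplotype that refines a large-effect marker class
    captures at least as many top-20% genotypes as the marker alone."""
    wins = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n = 200
        genos = [f"G{i:03d}" for i in range(n)]
        x1 = rng.binomial(1, 0.5, n)   # large effect
        x2 = rng.binomial(1, 0.5, n)   # planted secondary effect
        y = 0.45 - 0.14 * x1 - 0.05 * x2 + rng.normal(0, 0.08, n)
        blups = pd.DataFrame({"genotype_id": genos, "blup": y})
        marker_members = [g for g, v in zip(genos, x1) if v == 1]
        hap_members = [g for g, a, b in zip(genos, x1, x2) if a == 1 and b == 1]
        if not hap_members:
            continue
        cmp_ = selection_efficiency(hap_members, marker_members, blups)
        # overlap is compared as a proportion of each selected set
        frac_hap = cmp_.n_haplotype_in_top20 / cmp_.n_haplotype
        frac_marker = cmp_.n_marker_in_top20 / cmp_.n_marker
        if frac_hap >= frac_marker:
            wins += 1
    assert wins >= 0.80 * n_seeds


def test_empty_selection_sets_rejected():
    blups = pd.DataFrame({"genotype_id": ["G1", "G2"], "blup": [0.3, 0.4]})
    with pytest.raises(ValueError):
        selection_efficiency([], ["G1"], blups)
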