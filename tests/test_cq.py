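import numpy as np
import pandas as pd
import pytest

from helpers import make_matrix
from refstab.cq import (
    CqDataError,
    CqFormatError,
    CqMatrix,
    collapse_technical_reps,
    complete_case,
    cq_dispersion,
    read_cq_table,
    write_cq_table,
)
from refstab.simulate import default_panel, simulate_cq


def _well_table(tmp_path, rows, columns=None, name="cq.csv"):
    columns = columns or [
        "sample_id", "assay", "accession", "group", "time_min", "bio_rep", "tech_rep", "gene", "cq",
    ]
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def test_round_trip_preserves_cq_and_metadata(tmp_path):
    m, _ = simulate_cq(default_panel(seed=3))
    path = tmp_path / "cq.csv"
    write_cq_table(m, path)
    back = read_cq_table(path)
    assert back.genes == m.genes
    assert back.sample_ids == m.sample_ids
    np.testing.assert_allclose(back.cq.to_numpy(), m.cq.to_numpy(), rtol=1e-6)
    pd.testing.assert_frame_equal(back.samples, m.samples, check_dtype=False)


def test_two_gene_four_sample_csv_reads_as_2x4(tmp_path):
    rows = [
        [f"s{j}", "salt", "acc", "control", 0, j + 1, 1, g, 20.0 + j + 0.1 * i]
        for j in range(4)
        for i, g in enumerate(["ga", "gb"])
    ]
    m = read_cq_table(_well_table(tmp_path, rows))
    assert m.cq.shape == (2, 4)


def test_missing_gene_column_is_a_format_error(tmp_path):
    path = _well_table(
        tmp_path,
        [["s0", "salt", "acc", "control", 0, 1, 1, 20.0]],
        columns=["sample_id", "assay", "accession", "group", "time_min", "bio_rep", "tech_rep", "cq"],
    )
    with pytest.raises(CqFormatError, match="gene"):
        read_cq_table(path)


def test_duplicate_sample_gene_rows_are_a_data_error(tmp_path):
    rows = [
        ["s0", "salt", "acc", "control", 0, 1, 1, "ga", 20.0],
        ["s0", "salt", "acc", "control", 0, 1, 1, "ga", 21.0],
        ["s0", "salt", "acc", "control", 0, 1, 1, "gb", 20.0],
        ["s1", "salt", "acc", "control", 0, 2, 1, "ga", 20.0],
        ["s1", "salt", "acc", "control", 0, 2, 1, "gb", 20.0],
    ]
    with pytest.raises(CqDataError, match=r"s0.*ga|ga.*s0"):
        read_cq_table(_well_table(tmp_path, rows))


def test_unparseable_cq_rows_are_rejected_with_report(tmp_path):
    rows = [
        ["s0", "salt", "acc", "control", 0, 1, 1, "ga", "20.0"],
        ["s0", "salt", "acc", "control", 0, 1, 1, "gb", "oops"],
        ["s1", "salt", "acc", "control", 0, 2, 1, "ga", "21.0"],
        ["s1", "salt", "acc", "control", 0, 2, 1, "gb", "20.5"],
    ]
    report = tmp_path / "report.json"
    m = read_cq_table(_well_table(tmp_path, rows), report_path=report)
    assert m.cq.isna().sum().sum() == 1
    assert '"n_rejected": 1' in report.read_text()


@pytest.mark.parametrize(
    "tech_values, expected",
    [((20.0, 20.2, 20.4), 20.2), ((20.0, np.nan, np.nan), 20.0)],
)
def test_collapse_averages_non_missing_technical_cqs(tech_values, expected):
    vals = np.array([list(tech_values), [18.0, 18.0, 18.0]])
    meta = pd.DataFrame(
        {
            "assay": "salt", "accession": "acc", "group": "control",
            "time_min": 0, "bio_rep": 1, "tech_rep": [1, 2, 3],
        },
        index=pd.Index(["s0", "s1", "s2"], name="sample_id"),
    )
    m = CqMatrix(pd.DataFrame(vals, index=["ga", "gb"], columns=["s0", "s1", "s2"]), meta)
    out = collapse_technical_reps(m)
    assert out.n_samples == 1
    assert out.cq.loc["ga"].iloc[0] == pytest.approx(expected)


def test_collapse_three_by_three_design_gives_three_columns():
    cfg = default_panel(seed=0)
    m, _ = simulate_cq(cfg)
    per_cell = cfg.bio_reps * cfg.tech_reps
    out = collapse_technical_reps(m)
    assert out.n_samples == m.n_samples // cfg.tech_reps
    assert (out.samples["tech_rep"] == 0).all()


def test_dispersion_constant_gene_passes_and_spread_gene_fails():
    m = make_matrix([[20.0, 20.0, 20.0], [18.0, 22.0, np.nan]], genes=["flat", "spread"])
    disp = cq_dispersion(m).set_index("gene")
    assert disp.loc["flat", "sd"] == 0
    assert disp.loc["flat", "cv_pct"] == 0
    assert disp.loc["flat", "passes_screen"]
    # {18, 22}: ddof-1 SD = 2.828, CV = 14.14%
    assert disp.loc["spread", "sd"] == pytest.approx(2.828427, abs=1e-6)
    assert disp.loc["spread", "cv_pct"] == pytest.approx(14.142136, abs=1e-5)
    assert not disp.loc["spread", "passes_screen"]


def test_dispersion_sd_threshold_is_strict():
    m = make_matrix([[20.0, 20.0], [19.0, 21.0]], genes=["ok", "edge"])
    disp = cq_dispersion(m, sd_threshold=np.sqrt(2.0)).set_index("gene")
    assert not disp.loc["edge", "passes_screen"]  # sd == threshold fails


def test_dispersion_invariant_to_sample_order(panel_matrix):
    disp = cq_dispersion(panel_matrix).set_index("gene")["sd"]
    rng = np.random.default_rng(0)
    perm = rng.permutation(panel_matrix.sample_ids)
    shuffled = CqMatrix(panel_matrix.cq[perm], panel_matrix.samples.loc[perm])
    disp2 = cq_dispersion(shuffled).set_index("gene")["sd"]
    pd.testing.assert_series_equal(disp.sort_index(), disp2.sort_index())


def test_collapsing_reduces_dispersion_under_independent_tech_noise():
    # averaging independent technical noise shrinks the spread; checked
    # where the technical component is an appreciable share of the total
    from refstab.simulate import CqSimConfig, GeneSpec

    genes = [
        GeneSpec("g1", 18.0, 0.15), GeneSpec("g2", 19.0, 0.3), GeneSpec("g3", 20.0, 0.5),
        GeneSpec("g4", 21.0, 0.7), GeneSpec("g5", 22.0, 1.2),
    ]
    wins = total = 0
    for seed in range(100):
        cfg = CqSimConfig(genes=genes, sample_effect_sd=0.4, tech_noise_sd=0.6, seed=seed)
        m, _ = simulate_cq(cfg)
        before = cq_dispersion(m).set_index("gene")["sd"]
        after = cq_dispersion(collapse_technical_reps(m)).set_index("gene")["sd"]
        wins += int((after <= before).sum())
        total += len(before)
    assert wins / total >= 0.95


def test_complete_case_drops_samples_with_missing_genes():
    m = make_matrix([[20.0, np.nan, 20.0], [18.0, 19.0, 18.5]])
    out, n_dropped = complete_case(m)
    assert n_dropped == 1
    assert out.n_samples == 2


def test_all_missing_sample_is_rejected():
    with pytest.raises(CqDataError, match="no Cq observation"):
        make_matrix([[20.0, np.nan], [18.0, np.nan]])
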