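"""Motif discovery: catalog predicate, counting vs regex oracle,
enrichment behaviour, positional preference, EM elicitor."""

import numpy as np
import pandas as pd
import pytest

from _oracles import ga_rich_kmers, regex_count
from splicescreen import (
    count_occurrences,
    elicit_motif,
    enrichment,
    enumerate_filtered_kmers,
    positional_preference,
    scan_positions,
    select_event_sets,
    write_meme,
)


class TestCatalog:
    @pytest.mark.parametrize(
        "word,member",
        [
            ("GAGAGA", True),
            ("GGGGGG", False),  # no A
            ("GACTTT", False),  # G+A fraction 2/6
            ("GCAGGG", True),
            ("GCTGGA", True),
            ("AAAGGG", True),
        ],
    )
    def test_membership(self, word, member):
        assert (word in enumerate_filtered_kmers()) is member

    def test_equals_bruteforce_at_nondefault_parameters(self):
        cat = enumerate_filtered_kmers(k=4, min_g=2, min_a=1, min_ga_fraction=0.75)
        assert set(cat.kmers) == ga_rich_kmers(4, 2, 1, 0.75)

    def test_sorted_lexicographically(self):
        cat = enumerate_filtered_kmers()
        assert list(cat.kmers) == sorted(cat.kmers)

    def test_infeasible_filter_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            cat = enumerate_filtered_kmers(k=3, min_g=2, min_a=2)
        assert len(cat) == 0


class TestCounting:
    def test_overlapping_occurrences(self):
        tab = count_occurrences(("GAGAGA",), ["GAGAGAGA"]).set_index("kmer")
        assert tab.loc["GAGAGA", "count"] == 2

    def test_absent_word(self):
        tab = count_occurrences(("GAGAGA",), ["C" * 50]).set_index("kmer")
        assert tab.loc["GAGAGA", "count"] == 0

    def test_short_sequence_contributes_nothing(self):
        tab = count_occurrences(("GAGAGA",), ["GAG"])
        assert tab["count"].sum() == 0
        assert tab["kilobases"].iloc[0] == 0

    def test_n_windows_skipped(self):
        tab = count_occurrences(("GAGAGA",), ["GAGNGAGAGA"]).set_index("kmer")
        assert tab.loc["GAGAGA", "count"] == 1

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=200)) for _ in range(20)
        ]
        words = tuple(enumerate_filtered_kmers().kmers[::97])  # spread sample
        tab = count_occurrences(words, seqs).set_index("kmer")
        for w in words:
            assert tab.loc[w, "count"] == regex_count(w, seqs)

    def test_scan_positions_locates_hits(self):
        hits = scan_positions(("GAGAGA",), {"s1": "CCGAGAGACC"})
        assert hits.to_dict(orient="records") == [
            {"seq_id": "s1", "start": 2, "end": 8, "kmer": "GAGAGA"}
        ]


class TestEnrichment:
    def test_identical_sets_give_null_z(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(10)]
        res = enrichment(seqs, seqs, enumerate_filtered_kmers())
        assert res["z_score"].abs().max() < 1e-9

    def test_swap_flips_z_sign(self):
        rng = np.random.default_rng(6)
        fg = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(5)]
        bg = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(5)]
        words = ("GAGAGA", "GCAGGG")
        a = enrichment(fg, bg, words)
        b = enrichment(bg, fg, words).set_index("kmer")
        informative = a["foreground_freq"] != a["background_freq"]
        for _, row in a[informative].iterrows():
            assert np.sign(row["z_score"]) == -np.sign(
                b.loc[row["kmer"], "z_score"]
            )

    def test_planted_word_ranks_first(self):
        rng = np.random.default_rng(7)
        bg = ["".join(rng.choice(list("CT"), size=120)) for _ in range(30)]
        fg = [s[:40] + "GCAGGG" + s[46:] for s in bg]
        res = enrichment(fg, bg, enumerate_filtered_kmers())
        assert res.iloc[0]["kmer"] == "GCAGGG"
        assert res.iloc[0]["z_score"] > 0


class TestEventSelection:
    def _results(self, n, direction="activated"):
        return pd.DataFrame(
            {
                "event_id": [f"e{i:03d}" for i in range(n)],
                "category": "SE",
                "direction": direction,
                "q_value": np.linspace(1e-6, 0.04, n),
                "delta_psi": -0.4,
            }
        )

    def test_top_n_by_q(self):
        res = pd.concat([self._results(200), self._results(60, "repressed")])
        act, rep = select_event_sets(res, n_per_set=50)
        assert len(act) == 50 and len(rep) == 50
        assert act["q_value"].max() <= res[res["direction"] == "activated"][
            "q_value"
        ].nsmallest(50).max()

    def test_shortfall_takes_all_with_warning(self):
        res = self._results(30)
        with pytest.warns(UserWarning):
            act, rep = select_event_sets(res, n_per_set=50)
        assert len(act) == 30 and len(rep) == 0

    def test_tie_break_by_event_id(self):
        res = self._results(4)
        res["q_value"] = 0.01
        res["delta_psi"] = -0.3
        act, _ = select_event_sets(res, n_per_set=2)
        assert list(act["event_id"]) == ["e000", "e001"]

    def test_non_se_categories_excluded(self):
        res = self._results(10)
        res.loc[res.index[:5], "category"] = "MXE"
        act, _ = select_event_sets(res, n_per_set=3)
        assert len(act) == 3
        assert (act["category"] == "SE").all()


class TestPositionalPreference:
    def test_planted_truth_recovered(self, small_dataset, screened):
        truth = small_dataset.truth
        act_ids = truth.loc[truth["label"] == "activated", "event_id"]
        rep_ids = truth.loc[truth["label"] == "repressed", "event_id"]
        regions = ("upstream_flank", "cassette", "downstream_flank")
        seqs = small_dataset.sequences

        def collect(ids):
            return {r: [seqs[e][r] for e in ids] for r in regions}

        words = tuple(small_dataset.config.motifs.values())
        profile = positional_preference(collect(act_ids), collect(rep_ids), words)
        assert profile.preference["activated"] == "cassette"
        assert profile.preference["repressed"] == "flank"
        dens = profile.densities.set_index(["event_set", "region"])["density_per_kb"]
        assert dens["activated", "cassette"] > dens["activated", "upstream_flank"]
        assert dens["activated", "cassette"] > dens["activated", "downstream_flank"]

    def test_no_hits_flagged_undefined(self):
        empty = {r: ["CCCCCCCCCC"] for r in ("upstream_flank", "cassette", "downstream_flank")}
        profile = positional_preference(empty, empty, ("GAGAGA",))
        assert profile.preference == {"activated": None, "repressed": None}


class TestEm:
    @staticmethod
    def _planted(n=20, seed=4, word="GCAGGG", alphabet="CT"):
        rng = np.random.default_rng(seed)
        seqs = []
        for _ in range(n):
            s = "".join(rng.choice(list(alphabet), size=60))
            pos = int(rng.integers(0, 55))
            seqs.append(s[:pos] + word + s[pos + 6 :])
        return seqs

    def test_recovers_planted_consensus(self):
        model = elicit_motif(self._planted(), init_kmer="GCAGGG")
        assert model.consensus == "GCAGGG"

    def test_recovers_without_seed_kmer(self):
        # on a uniform background the planted word is the most frequent
        # hexamer, so the default deterministic init suffices
        model = elicit_motif(self._planted(seed=9, alphabet="ACGT"))
        assert model.consensus == "GCAGGG"

    def test_loglik_monotone_and_columns_normalized(self):
        model = elicit_motif(self._planted(seed=2), init_kmer="GCAGGG")
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert np.allclose(model.pwm.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_sequences_yield_substring_consensus(self):
        rng = np.random.default_rng(13)
        w = "".join(rng.choice(list("ACGT"), size=30))
        model = elicit_motif([w] * 5, init_kmer=None)
        substrings = {w[i : i + 6] for i in range(len(w) - 5)}
        assert model.consensus in substrings

    def test_short_sequence_error_names_offender(self):
        with pytest.raises(ValueError, match="#1"):
            elicit_motif(["ACGTACGTAC", "ACG"], width=6)

    def test_meme_output_format(self, tmp_path):
        model = elicit_motif(self._planted(), init_kmer="GCAGGG")
        out = tmp_path / "m.meme"
        write_meme(model, out)
        text = out.read_text()
        assert text.startswith("MEME version")
        assert "letter-probability matrix" in text
        rows = [l for l in text.splitlines() if l and l[0].isdigit()]
        assert len(rows) == 6
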