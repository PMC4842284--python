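import itertools

import numpy as np
import pytest

from midflux.core import write_mid_table
from midflux.simulate import (
    ModelError,
    compile_model,
    fragment_mid,
    generate_dataset,
    load_model,
    simulate_labeling,
    total_mid,
)


def linear_chain_spec(n=3):
    compounds = {f"X{i}": 2 for i in range(n)}
    reactions = [
        {
            "id": f"r{i}",
            "type": "transfer",
            "product": f"X{i}",
            "substrates": [{"compound": f"X{i-1}", "map": {0: 0, 1: 1}}],
        }
        for i in range(1, n)
    ]
    return {
        "compounds": compounds,
        "reactions": reactions,
        "sources": {"X0": {"10": 0.5, "00": 0.5}},
    }


class TestCompileModel:
    def test_linear_chain_valid(self):
        model = compile_model(linear_chain_spec())
        assert set(model.compounds) == {"X0", "X1", "X2"}
        # single-producer compounds get implicit mixing fraction 1
        assert model.mixing["X1"] == [("r1", 1.0)]

    def test_bad_mixing_fractions(self):
        spec = linear_chain_spec()
        spec["mixing"] = {"X1": [{"reaction": "r1", "fraction": 0.6}]}
        spec["reactions"].append(
            {
                "id": "r1b",
                "type": "transfer",
                "product": "X1",
                "substrates": [{"compound": "X0", "map": {0: 0, 1: 1}}],
            }
        )
        spec["mixing"]["X1"].append({"reaction": "r1b", "fraction": 0.5})
        with pytest.raises(ModelError, match="sum"):
            compile_model(spec)

    def test_condensation_concatenating_map(self):
        spec = {
            "compounds": {"A": 2, "B": 4, "C": 6},
            "reactions": [
                {
                    "id": "cond",
                    "type": "condensation",
                    "product": "C",
                    "substrates": [
                        {"compound": "A", "map": {0: 0, 1: 1}},
                        {"compound": "B", "map": {0: 2, 1: 3, 2: 4, 3: 5}},
                    ],
                }
            ],
            "sources": {"A": {"11": 1.0}, "B": "unlabeled"},
        }
        model = compile_model(spec)
        rxn = model.reactions["cond"]
        assert rxn.substrates[0][1] == {0: 0, 1: 1}
        assert rxn.substrates[1][1] == {0: 2, 1: 3, 2: 4, 3: 5}

    def test_dangling_compound_rejected(self):
        spec = linear_chain_spec()
        spec["reactions"][0]["substrates"][0]["compound"] = "GHOST"
        with pytest.raises(ModelError, match="dangling"):
            compile_model(spec)

    def test_non_bijective_map_rejected(self):
        spec = linear_chain_spec()
        spec["reactions"][0]["substrates"][0]["map"] = {0: 0, 1: 0}
        with pytest.raises(ModelError, match="bijection|mapped twice"):
            compile_model(spec)

    def test_unmapped_product_atom_rejected(self):
        spec = linear_chain_spec()
        spec["reactions"][0]["substrates"][0]["map"] = {0: 0}
        with pytest.raises(ModelError, match="unmapped"):
            compile_model(spec)

    def test_orphan_compound_rejected(self):
        spec = linear_chain_spec()
        spec["compounds"]["LONER"] = 2
        with pytest.raises(ModelError, match="no producing reaction"):
            compile_model(spec)

    def test_toy_model_loads(self, toy_model):
        assert "CIT" in toy_model.compounds
        assert set(toy_model.tracers) == {"glc", "gln"}


class TestSimulateLabeling:
    def test_transfer_preserves_labeling(self):
        model = compile_model(linear_chain_spec(4))
        state = simulate_labeling(model)
        for name in ("X1", "X2", "X3"):
            assert np.allclose(state[name], state["X0"], atol=1e-12)

    def test_mixing_linearity_closed_form(self):
        spec = {
            "compounds": {"A": 2, "A2": 2, "B": 2},
            "reactions": [
                {"id": "ra", "type": "transfer", "product": "B",
                 "substrates": [{"compound": "A", "map": {0: 0, 1: 1}}]},
                {"id": "rb", "type": "transfer", "product": "B",
                 "substrates": [{"compound": "A2", "map": {0: 0, 1: 1}}]},
            ],
            "mixing": {"B": [
                {"reaction": "ra", "fraction": 0.6},
                {"reaction": "rb", "fraction": 0.4},
            ]},
            "sources": {"A": {"11": 1.0}, "A2": "unlabeled"},
        }
        state = simulate_labeling(compile_model(spec))
        mid_a = total_mid(state, "A").as_array()
        mid_a2 = total_mid(state, "A2").as_array()
        expected = 0.6 * mid_a + 0.4 * mid_a2
        assert np.allclose(total_mid(state, "B").as_array(), expected, atol=1e-12)

    def test_condensation_equals_convolution(self):
        spec = {
            "compounds": {"A": 2, "B": 2, "C": 4},
            "reactions": [
                {"id": "cond", "type": "condensation", "product": "C",
                 "substrates": [
                     {"compound": "A", "map": {0: 0, 1: 1}},
                     {"compound": "B", "map": {0: 2, 1: 3}},
                 ]},
            ],
            "sources": {"A": {"10": 0.7, "00": 0.3}, "B": {"11": 0.2, "00": 0.8}},
        }
        state = simulate_labeling(compile_model(spec))
        conv = np.convolve(
            total_mid(state, "A").as_array(), total_mid(state, "B").as_array()
        )
        assert np.allclose(total_mid(state, "C").as_array(), conv, atol=1e-12)

    def test_distributions_sum_to_one(self, toy_model):
        state = simulate_labeling(toy_model, source_overrides=toy_model.tracers["glc"])
        for vec in state.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert (vec >= -1e-15).all()

    def test_acyclic_fixed_point_in_path_length_iterations(self):
        n = 6
        model = compile_model(linear_chain_spec(n))
        # state is exact after n-1 sweeps; one more detects the fixed point
        state = simulate_labeling(model, max_iter=n)
        assert np.allclose(state[f"X{n-1}"], state["X0"], atol=1e-12)

    def test_cyclic_model_converges(self, toy_model):
        state = simulate_labeling(
            toy_model, source_overrides=toy_model.tracers["gln"]
        )
        assert total_mid(state, "GLU").as_array()[-1] == pytest.approx(1.0)

    def test_nonconvergence_reported(self):
        model = compile_model(linear_chain_spec(5))
        with pytest.raises(ModelError, match="converge"):
            simulate_labeling(model, max_iter=2)


class TestFragmentMid:
    def test_full_subset_equals_total_mid_by_popcount(self):
        rng = np.random.default_rng(31)
        dist = rng.dirichlet(np.ones(8))
        state = {"X": dist}
        out = fragment_mid(state, "X", [0, 1, 2]).as_array()
        # definitional oracle: aggregate isotopomer probabilities by popcount
        oracle = np.zeros(4)
        for idx, p in enumerate(dist):
            oracle[bin(idx).count("1")] += p
        assert np.allclose(out, oracle, atol=1e-12)

    def test_unlabeled_subset(self):
        dist = np.zeros(8)
        dist[0] = 1.0
        out = fragment_mid({"X": dist}, "X", [0, 2])
        assert out.abundances == pytest.approx((1.0, 0.0, 0.0))

    def test_hand_marginalization(self):
        # 3-atom distribution: P(000)=0.4, P(101)=0.35, P(011)=0.25
        dist = np.zeros(8)
        dist[0b000] = 0.4
        dist[0b101] = 0.35
        dist[0b011] = 0.25
        # subset {atoms 0,1}: 000 -> 0 labels; 101 -> atom0 labeled (1);
        # 011 -> atoms 0,1 labeled (2)
        out = fragment_mid({"X": dist}, "X", [0, 1]).as_array()
        assert np.allclose(out, [0.4, 0.35, 0.25], atol=1e-12)

    def test_empty_subset(self):
        out = fragment_mid({"X": np.array([0.5, 0.5])}, "X", [])
        assert out.abundances == (1.0,)

    def test_invalid_atom_rejected(self):
        with pytest.raises(ValueError):
            fragment_mid({"X": np.array([0.5, 0.5])}, "X", [3])


class TestGenerateDataset:
    def test_noiseless_equals_ground_truth(self, toy_model):
        ds, truth = generate_dataset(
            toy_model, [("base", {})], ["glc"], noise_sd=0.0, replicates=2, seed=1
        )
        for (cond, tracer), comp_map in truth.mids.items():
            for comp, frag_map in comp_map.items():
                for mz, true_mid in frag_map.items():
                    for rec in ds.records_for(comp, cond, tracer):
                        got = rec.fragment(mz).mid
                        assert np.allclose(
                            got.as_array(), true_mid.as_array(), atol=1e-12
                        )

    def test_same_seed_identical(self, toy_model):
        kw = dict(
            conditions=[("base", {})],
            tracers=["glc"],
            noise_sd=0.01,
            natural_abundance=True,
            replicates=2,
        )
        ds1, _ = generate_dataset(toy_model, seed=42, **kw)
        ds2, _ = generate_dataset(toy_model, seed=42, **kw)
        for key in ds1.sample_keys():
            for cid, rec in ds1.entries[key].items():
                rec2 = ds2.entries[key][cid]
                for f1 in rec.fragments:
                    f2 = rec2.fragment(f1.fragment_mz)
                    assert f1.mid.abundances == f2.mid.abundances
                    assert f1.raw_intensities == f2.raw_intensities

    def test_different_seed_differs(self, toy_model):
        kw = dict(
            conditions=[("base", {})], tracers=["glc"], noise_sd=0.01, replicates=1
        )
        ds1, _ = generate_dataset(toy_model, seed=1, **kw)
        ds2, _ = generate_dataset(toy_model, seed=2, **kw)
        diffs = [
            f1.mid.abundances != ds2.entries[key][cid].fragment(f1.fragment_mz).mid.abundances
            for key in ds1.sample_keys()
            for cid, rec in ds1.entries[key].items()
            for f1 in rec.fragments
        ]
        assert any(diffs)

    def test_negative_noise_rejected(self, toy_model):
        with pytest.raises(ValueError):
            generate_dataset(toy_model, [("b", {})], ["glc"], noise_sd=-0.1)

    def test_unknown_tracer_rejected(self, toy_model):
        with pytest.raises(ModelError, match="tracer"):
            generate_dataset(toy_model, [("b", {})], ["fructose"])

    def test_emitted_table_round_trips(self, toy_model, tmp_path):
        from midflux.core import read_mid_table

        ds, _ = generate_dataset(
            toy_model, [("base", {})], ["glc", "gln"],
            noise_sd=0.005, natural_abundance=True, replicates=2, seed=3,
        )
        path = tmp_path / "sim.tsv"
        write_mid_table(ds, path)
        back = read_mid_table(path)
        assert back.n_compounds() == ds.n_compounds()

    def test_pathway_separation(self, parallel_pathways_model):
        from midflux.similarity import mid_distance

        state = simulate_labeling(parallel_pathways_model)
        groups = {
            "A": ["SA", "A1", "A2", "A3"],
            "B": ["SB", "B1", "B2", "B3"],
        }
        mids = {
            c: total_mid(state, c)
            for c in groups["A"] + groups["B"]
        }
        within, between = [], []
        for x, y in itertools.combinations(mids, 2):
            d = mid_distance(mids[x], mids[y])
            same = any(x in g and y in g for g in groups.values())
            (within if same else between).append(d)
        assert np.mean(within) < np.mean(between)
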