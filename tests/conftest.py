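import numpy as np
import pytest

from midflux import load_toy_model
from midflux.core import (
    MID,
    CompoundRecord,
    FragmentMeasurement,
    LabelingDataset,
)


@pytest.fixture(scope="session")
def toy_model():
    return load_toy_model()


def make_fragment(mz, abundances, r2=0.99, raw=None, formula=None):
    return FragmentMeasurement(
        fragment_mz=mz,
        mid=MID(tuple(abundances)),
        r2=r2,
        raw_intensities=raw,
        formula=formula,
    )


def make_record(cid, frags, name=None, ri=None):
    return CompoundRecord(
        compound_id=cid, fragments=tuple(frags), name=name, retention_index=ri
    )


@pytest.fixture
def small_dataset():
    """Two compounds, two conditions, two replicates, one tracer."""
    ds = LabelingDataset()
    for cond, shift in [("A", 0.0), ("B", 0.1)]:
        for rep in (1, 2):
            ds.add(
                cond,
                "glc",
                rep,
                make_record(
                    "cmp1",
                    [
                        make_fragment(245, [0.6 - shift, 0.3, 0.1 + shift]),
                        make_fragment(304, [0.7 - shift, 0.2, 0.1 + shift]),
                    ],
                    name="alanine",
                    ri=1100.0,
                ),
            )
            ds.add(
                cond,
                "glc",
                rep,
                make_record(
                    "cmp2",
                    [make_fragment(174, [0.8, 0.15, 0.05])],
                    ri=1500.0,
                ),
            )
    return ds


def random_mid(rng, length):
    v = rng.dirichlet(np.ones(length))
    return MID(tuple(v))


def parallel_pathways_spec():
    """Two parallel linear 4-compound pathways fed by distinct sources.

    Each step dilutes with 15% unlabeled carbon so MIDs drift gradually
    within a pathway while the two pathways keep distinct shapes.
    """
    compounds = {"U3": 3, "SA": 3, "SB": 3}
    reactions = []
    mixing = {}
    chain = {"SA": ["A1", "A2", "A3"], "SB": ["B1", "B2", "B3"]}
    for src, members in chain.items():
        prev = src
        for name in members:
            compounds[name] = 3
            rid_main = f"{prev}_to_{name}"
            rid_dil = f"dil_{name}"
            reactions.append(
                {
                    "id": rid_main,
                    "type": "transfer",
                    "product": name,
                    "substrates": [
                        {"compound": prev, "map": {0: 0, 1: 1, 2: 2}}
                    ],
                }
            )
            reactions.append(
                {
                    "id": rid_dil,
                    "type": "transfer",
                    "product": name,
                    "substrates": [
                        {"compound": "U3", "map": {0: 0, 1: 1, 2: 2}}
                    ],
                }
            )
            mixing[name] = [
                {"reaction": rid_main, "fraction": 0.85},
                {"reaction": rid_dil, "fraction": 0.15},
            ]
            prev = name
    return {
        "compounds": compounds,
        "reactions": reactions,
        "mixing": mixing,
        "sources": {
            "U3": "unlabeled",
            "SA": {"110": 0.5, "000": 0.5},
            "SB": {"000": 0.1, "100": 0.3, "110": 0.3, "111": 0.3},
        },
        "tracers": {"mix": {}},
    }


@pytest.fixture(scope="session")
def parallel_pathways_model():
    from midflux.simulate import compile_model

    return compile_model(parallel_pathways_spec())
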