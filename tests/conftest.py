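import numpy as np
import pytest

from gocellmap.ontology import OntologyDAG
from gocellmap.synthetic import make_ontology, make_species_pair


def dag_from_parents(parents: dict[str, set[str]], **kwargs) -> OntologyDAG:
    """Build a DAG directly from a parent map (all biological_process)."""
    terms = set(parents)
    for ps in parents.values():
        terms |= set(ps)
    full = {t: set(parents.get(t, ())) for t in terms}
    return OntologyDAG(
        terms=terms,
        parents=full,
        namespace={t: "biological_process" for t in terms},
        **kwargs,
    )


@pytest.fixture
def chain_dag():
    """t3 -> t2 -> t1 (t1 is the root)."""
    return dag_from_parents({"t3": {"t2"}, "t2": {"t1"}, "t1": set()})


@pytest.fixture
def diamond_dag():
    """t4 -> {t2, t3} -> t1."""
    return dag_from_parents({"t4": {"t2", "t3"}, "t2": {"t1"}, "t3": {"t1"}})


def brute_force_ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """Independent reachability oracle: naive recursive closure."""

    def walk(t):
        out = set()
        for p in dag.parents.get(t, ()):
            out.add(p)
            out |= walk(p)
        return out

    return walk(term)


def brute_force_minimal(dag: OntologyDAG, terms: set[str]) -> set[str]:
    """Independent antichain oracle: pairwise ancestor checks."""
    terms = set(terms)
    return {
        t
        for t in terms
        if not any(t in brute_force_ancestors(dag, other) for other in terms - {t})
    }


@pytest.fixture(scope="session")
def small_truth():
    """One synthetic species pair shared by read-only tests."""
    dag = make_ontology(n_terms=60, seed=11)
    return make_species_pair(
        dag,
        n_cell_types=4,
        cells_per_type=40,
        genes_per_species=250,
        terms_per_type=5,
        signal_fold=8.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_profiles(small_truth):
    """Normalized+scaled profiles for both synthetic species."""
    from gocellmap.annotations import build_binary_matrix
    from gocellmap.profile import build_profile, normalize, scale

    profs = {}
    for sp in small_truth.species:
        bam = build_binary_matrix(
            small_truth.annotations[sp],
            small_truth.ontology,
            gene_universe=small_truth.counts[sp].genes,
        )
        profs[sp] = scale(normalize(build_profile(small_truth.counts[sp], bam)))
    return profs


def random_parent_map(rng: np.random.Generator, n_terms: int) -> dict[str, set[str]]:
    """Random acyclic parent map: parents only among earlier terms."""
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    parents = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i) + 1))
        parents[ids[i]] = set(rng.choice(ids[:i], size=k, replace=False))
    return parents
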