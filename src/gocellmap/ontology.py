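"""Gene Ontology DAG: OBO parsing and the hierarchy-handling operations.

The ontology is held as a parent map over non-obsolete terms. Three
operations on it underpin cross-species signature extraction:

* :func:`ancestors` — transitive closure over the selected relations;
* :func:`minimal_set` — reduce a term set to its most specific members
  (drop every term that has a descendant also present in the set), yielding
  an antichain;
* :func:`harmonize_lists` — represent two species' term lists by their
  intersection plus, for ancestor/descendant pairs split across the lists,
  the ancestor — so a species annotated at coarser granularity does not
  hide biology shared with a finely annotated one.

Only direct ancestor/descendant pairs between the two lists are merged;
no deeper common ancestor of two unrelated terms is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import FormatError, IntegrityError, LookupError_, UsageError

VALID_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class OntologyDAG:
    """Directed acyclic graph of GO terms.

    ``parents[t]`` holds the direct parents of ``t`` via the relations the
    DAG was built with. Obsolete terms are recorded but excluded from
    ``terms`` and from traversal. ``alt_ids`` maps merged/secondary ids to
    their primary term.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    relations: frozenset[str] = frozenset({"is_a"})

    def resolve(self, term: str) -> str:
        """Map ``term`` through alt_ids to a primary id, or raise."""
        if term in self.terms:
            return term
        primary = self.alt_ids.get(term)
        if primary is not None and primary in self.terms:
            return primary
        raise LookupError_(f"unknown GO term: {term!r}")

    def children_map(self) -> dict[str, set[str]]:
        """Invert the parent map (computed on demand)."""
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        return children


@dataclass(frozen=True)
class HarmonizedTerm:
    """One representative term with its contributing source term per list."""

    term: str
    from_a: frozenset[str]
    from_b: frozenset[str]


def parse_obo(path, relations: Iterable[str] = ("is_a",)) -> OntologyDAG:
    """Parse an OBO 1.4 file into an :class:`OntologyDAG`.

    Parameters
    ----------
    path
        Filesystem path (or open text handle) of the OBO file.
    relations
        Which edge types to traverse; subset of ``{"is_a", "part_of"}``.
        The default follows the convention of only walking ``is_a``;
        ``part_of`` changes ancestor sets and must be an explicit choice.
    """
    rels = frozenset(relations)
    if not rels:
        raise UsageError("at least one relation must be selected")
    unknown = rels - VALID_RELATIONS
    if unknown:
        raise UsageError(f"unsupported relations: {sorted(unknown)}")

    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except OSError:
        raise
    except Exception as exc:  # malformed stanza etc.
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc

    obsolete = {
        n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"
    }
    terms = set(graph.nodes) - obsolete
    namespace = {}
    names = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if node in obsolete:
            continue
        namespace[node] = data.get("namespace", "biological_process")
        if "name" in data:
            names[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    parents: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, key in graph.edges(keys=True):
        if key not in rels:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in terms:
            continue
        parents[child].add(parent)

    # cycle check on the selected relations only
    sub = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise IntegrityError(f"ontology contains a cycle through {cycle[0][0]}")

    return OntologyDAG(
        terms=terms,
        parents=parents,
        namespace=namespace,
        names=names,
        alt_ids=alt_ids,
        obsolete=obsolete,
        relations=rels,
    )


def ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """All terms reachable from ``term`` by following parents; excludes ``term``."""
    start = dag.resolve(term)
    seen: set[str] = set()
    stack = list(dag.parents.get(start, ()))
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(dag.parents.get(t, ()))
    return seen


def minimal_set(dag: OntologyDAG, terms: Iterable[str]) -> set[str]:
    """Retain only the most specific terms of ``terms``.

    A term is dropped iff another member of the input set is its
    descendant; the result is an antichain under the ancestor relation.
    """
    resolved = {dag.resolve(t) for t in terms}
    # union of ancestors of all members = the members that are "covered"
    covered: set[str] = set()
    for t in resolved:
        covered |= ancestors(dag, t)
    return {t for t in resolved if t not in covered}


def harmonize_lists(
    dag: OntologyDAG, terms_a: Iterable[str], terms_b: Iterable[str]
) -> set[HarmonizedTerm]:
    """Shared representation of two term lists.

    Emits (i) every term in the intersection, paired with itself on both
    sides, and (ii) for every cross-list ancestor/descendant pair, the
    ancestor as representative with the descendant recorded as the source
    term of its list. Deduplicated by representative id, keeping all source
    contributions.
    """
    set_a = {dag.resolve(t) for t in terms_a}
    set_b = {dag.resolve(t) for t in terms_b}

    anc_a = {t: ancestors(dag, t) for t in set_a}
    anc_b = {t: ancestors(dag, t) for t in set_b}

    from_a: dict[str, set[str]] = {}
    from_b: dict[str, set[str]] = {}

    for t in set_a & set_b:
        from_a.setdefault(t, set()).add(t)
        from_b.setdefault(t, set()).add(t)
    for b, anc in anc_b.items():
        for a in set_a & anc:  # a is an ancestor of b
            from_a.setdefault(a, set()).add(a)
            from_b.setdefault(a, set()).add(b)
    for a, anc in anc_a.items():
        for b in set_b & anc:  # b is an ancestor of a
            from_b.setdefault(b, set()).add(b)
            from_a.setdefault(b, set()).add(a)

    return {
        HarmonizedTerm(term=t, from_a=frozenset(from_a[t]), from_b=frozenset(from_b[t]))
        for t in from_a
    }
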