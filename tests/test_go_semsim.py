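import itertools

import numpy as np
import pytest

from edgefill import parse_obo, protein_go_sim, read_gaf, svalues, term_sim
from edgefill.go_semsim import AnnotationMap, GoDag, TermInfo


# ---------------------------------------------------------------- oracles
def all_paths_svalues(anchor, dag):
    """Brute-force oracle: S(t) = max over all directed anchor->t parent
    paths of the product of edge weights."""
    out = {anchor: 1.0}

    def walk(term, product):
        for pid, rel in dag.terms[term].parents:
            p = product * dag.weights[rel]
            if p > out.get(pid, 0.0):
                out[pid] = p
            walk(pid, p)

    walk(anchor, 1.0)
    return out


def oracle_term_sim(a, b, dag):
    sa, sb = all_paths_svalues(a, dag), all_paths_svalues(b, dag)
    shared = sa.keys() & sb.keys()
    return sum(sa[t] + sb[t] for t in shared) / (
        sum(sa.values()) + sum(sb.values())
    )


def random_dag(rng, n_terms):
    """Random single-namespace DAG: term i may have parents among 0..i-1."""
    terms = {"T:000": TermInfo(namespace="BP", parents=())}
    ids = ["T:000"]
    for i in range(1, n_terms):
        tid = f"T:{i:03d}"
        k = int(rng.integers(1, min(3, i) + 1))
        parents = tuple(
            (ids[int(j)], "is_a" if rng.random() < 0.7 else "part_of")
            for j in rng.choice(i, size=k, replace=False)
        )
        terms[tid] = TermInfo(namespace="BP", parents=parents)
        ids.append(tid)
    return GoDag(terms=terms), ids


# ---------------------------------------------------------------- parsing
class TestParseObo:
    def test_toy_ontology_structure(self, toy_obo_path):
        dag = parse_obo(toy_obo_path)
        assert len(dag.terms) == 5
        links = [
            (t, p, rel)
            for t, info in dag.terms.items()
            for p, rel in info.parents
        ]
        assert ("T:0002", "T:0001", "is_a") in links
        assert ("T:0004", "T:0002", "part_of") in links
        assert len(links) == 4  # incl. the obsolete term's is_a

    def test_alt_id_resolves_to_primary(self, toy_obo_path):
        dag = parse_obo(toy_obo_path)
        assert dag.resolve("T:0099") == "T:0002"

    def test_obsolete_term_excluded_from_resolution(self, toy_obo_path):
        dag = parse_obo(toy_obo_path)
        assert dag.terms["T:0005"].obsolete
        assert dag.resolve("T:0005") is None

    def test_cycle_detection_names_a_term(self):
        with pytest.raises(ValueError, match="cycle"):
            GoDag(
                terms={
                    "T:a": TermInfo(namespace="BP", parents=(("T:b", "is_a"),)),
                    "T:b": TermInfo(namespace="BP", parents=(("T:a", "is_a"),)),
                }
            )


GAF = """!gaf-version: 2.1
TOY\tP1\tP1\t\tT:0002\tREF:1\tIDA\t\tP\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
TOY\tP1\tP1\t\tT:0003\tREF:1\tIDA\t\tF\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
TOY\tP2\tP2\tNOT\tT:0002\tREF:1\tIDA\t\tP\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
TOY\tP3\tP3\t\tT:0099\tREF:1\tIEA\t\tP\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
TOY\tP3\tP3\t\tT:0002\tREF:1\tIDA\t\tP\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
TOY\tP4\tP4\t\tT:0005\tREF:1\tIDA\t\tP\t\t\tprotein\ttaxon:4932\t20160305\tTOY\t\t
"""


class TestReadGaf:
    @pytest.fixture()
    def gaf_path(self, tmp_path):
        p = tmp_path / "toy.gaf"
        p.write_text(GAF)
        return p

    def test_aspect_filter(self, toy_obo_path, gaf_path):
        dag = parse_obo(toy_obo_path)
        ann = read_gaf(gaf_path, "BP", dag)
        assert ann.terms_for("P1") == {"T:0002"}  # the F-aspect row dropped

    def test_not_qualifier_dropped(self, toy_obo_path, gaf_path):
        ann = read_gaf(gaf_path, "BP", parse_obo(toy_obo_path))
        assert "P2" not in ann

    def test_alt_id_mapped_and_duplicates_collapse(self, toy_obo_path, gaf_path):
        # P3 annotated to alt id T:0099 (-> T:0002) and to T:0002 directly
        ann = read_gaf(gaf_path, "BP", parse_obo(toy_obo_path))
        assert ann.terms_for("P3") == {"T:0002"}

    def test_obsolete_rows_dropped(self, toy_obo_path, gaf_path):
        ann = read_gaf(gaf_path, "BP", parse_obo(toy_obo_path))
        assert "P4" not in ann

    def test_evidence_exclusion_flag(self, toy_obo_path, gaf_path):
        ann = read_gaf(gaf_path, "BP", parse_obo(toy_obo_path),
                       exclude_evidence={"IEA"})
        assert ann.terms_for("P3") == {"T:0002"}  # only the IEA row dropped


# ---------------------------------------------------------------- S-values
class TestSvalues:
    def test_single_chain_products(self):
        dag = GoDag(
            terms={
                "T:root": TermInfo(namespace="BP", parents=()),
                "T:p": TermInfo(namespace="BP", parents=(("T:root", "is_a"),)),
                "T:a": TermInfo(namespace="BP", parents=(("T:p", "is_a"),)),
            }
        )
        assert svalues("T:a", dag) == pytest.approx(
            {"T:a": 1.0, "T:p": 0.8, "T:root": 0.8 * 0.8}
        )

    def test_diamond_takes_maximum_path(self):
        # root reached via is_a/is_a (0.64) and via part_of/is_a (0.48)
        dag = GoDag(
            terms={
                "T:root": TermInfo(namespace="BP", parents=()),
                "T:l": TermInfo(namespace="BP", parents=(("T:root", "is_a"),)),
                "T:r": TermInfo(namespace="BP", parents=(("T:root", "is_a"),)),
                "T:a": TermInfo(
                    namespace="BP",
                    parents=(("T:l", "is_a"), ("T:r", "part_of")),
                ),
            }
        )
        s = svalues("T:a", dag)
        assert s["T:root"] == pytest.approx(0.8 * 0.8)
        assert s == pytest.approx(all_paths_svalues("T:a", dag))

    def test_root_anchor_is_identity(self, toy_dag):
        assert svalues("T:root", toy_dag) == {"T:root": 1.0}

    def test_unknown_term_raises(self, toy_dag):
        with pytest.raises(KeyError):
            svalues("T:nope", toy_dag)

    def test_matches_all_paths_oracle_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            dag, ids = random_dag(rng, int(rng.integers(5, 31)))
            anchor = ids[int(rng.integers(1, len(ids)))]
            got = svalues(anchor, dag)
            want = all_paths_svalues(anchor, dag)
            assert got.keys() == want.keys()
            for t in want:
                assert got[t] == pytest.approx(want[t], abs=1e-12)


# ---------------------------------------------------------------- term sim
class TestTermSim:
    def test_self_similarity_is_one(self, toy_dag):
        assert term_sim("T:d", "T:d", toy_dag) == pytest.approx(1.0)

    def test_leaves_sharing_only_root(self, toy_dag):
        # T:d path sums: 1 + 0.8 + 0.64; T:e: 1 + 0.6 + 0.48
        got = term_sim("T:d", "T:e", toy_dag)
        assert got == pytest.approx(oracle_term_sim("T:d", "T:e", toy_dag))
        expected = (0.64 + 0.48) / ((1 + 0.8 + 0.64) + (1 + 0.6 + 0.48))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_siblings_under_one_parent(self, toy_dag):
        got = term_sim("T:b", "T:c", toy_dag)
        assert got == pytest.approx(oracle_term_sim("T:b", "T:c", toy_dag))

    def test_cross_namespace_pair_rejected(self):
        dag = GoDag(
            terms={
                "T:bp": TermInfo(namespace="BP", parents=()),
                "T:mf": TermInfo(namespace="MF", parents=()),
            }
        )
        with pytest.raises(ValueError, match="namespace"):
            term_sim("T:bp", "T:mf", dag)


# ------------------------------------------------------------- protein sim
class TestProteinGoSim:
    def test_identical_annotation_sets_score_one(self, toy_dag):
        ann = AnnotationMap(annotations={"u": {"T:d"}, "v": {"T:d"}})
        assert protein_go_sim("u", "v", ann, toy_dag) == pytest.approx(1.0)

    def test_unannotated_protein_scores_zero(self, toy_dag):
        ann = AnnotationMap(annotations={"u": {"T:d"}})
        assert protein_go_sim("u", "v", ann, toy_dag) == 0.0

    def test_single_term_case_reduces_to_term_sim(self, toy_dag):
        ann = AnnotationMap(annotations={"u": {"T:d"}, "v": {"T:e"}})
        assert protein_go_sim("u", "v", ann, toy_dag) == pytest.approx(
            term_sim("T:d", "T:e", toy_dag), abs=1e-12
        )

    def test_symmetric_and_bounded(self, toy_dag):
        ann = AnnotationMap(
            annotations={"u": {"T:d", "T:c"}, "v": {"T:e"}, "w": {"T:b", "T:e"}}
        )
        for a, b in itertools.combinations(["u", "v", "w"], 2):
            s_ab = protein_go_sim(a, b, ann, toy_dag)
            s_ba = protein_go_sim(b, a, ann, toy_dag)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert 0.0 <= s_ab <= 1.0

    def test_monotone_dilution_by_unrelated_branch(self):
        """Adding an unrelated annotation branch to v never raises the
        similarity to a fixed, disjoint u."""
        terms = {"T:root": TermInfo(namespace="BP", parents=())}
        for name in ("a", "b", "c"):
            terms[f"T:{name}"] = TermInfo(
                namespace="BP", parents=(("T:root", "is_a"),)
            )
            terms[f"T:{name}leaf"] = TermInfo(
                namespace="BP", parents=((f"T:{name}", "is_a"),)
            )
        dag = GoDag(terms=terms)
        ann0 = AnnotationMap(annotations={"u": {"T:aleaf"}, "v": {"T:bleaf"}})
        ann1 = AnnotationMap(
            annotations={"u": {"T:aleaf"}, "v": {"T:bleaf", "T:cleaf"}}
        )
        assert protein_go_sim("u", "v", ann1, dag) <= protein_go_sim(
            "u", "v", ann0, dag
        ) + 1e-12

    def test_direct_terms_mode_is_dice_overlap(self, toy_dag):
        ann = AnnotationMap(annotations={"u": {"T:d", "T:b"}, "v": {"T:d"}})
        got = protein_go_sim("u", "v", ann, toy_dag, include_ancestors=False)
        assert got == pytest.approx(2 * 1 / (2 + 1))
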