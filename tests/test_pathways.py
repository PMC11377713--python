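"""Hypergeometric overrepresentation and miRNA->gene link detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triomics.diffexpr import differential_expression
from triomics.io import PathwayDB, PeptideEntry, PeptideMap, TargetMap
from triomics.pathways import (detect_links, extend_pathway, ora,
                               overrepresented_pathways,
                               pathway_link_analysis)
from triomics.preprocess import summarize_peptides


def _db(sets):
    return PathwayDB({k: k for k in sets}, {k: set(v) for k, v in sets.items()})


def _de(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "p_value"])
    df["coef"] = df["log2fc"]
    df["se"] = 1.0
    df["p_adjusted"] = df["p_value"]
    df["significant"] = df["p_value"] < 0.05
    return df


class TestOra:
    def test_p_matches_enumeration_oracle(self):
        """Exhaustive enumeration over all C(10, 4) query draws."""
        background = [f"g{i}" for i in range(10)]
        pathway = set(background[:5])
        query = set(background[2:6])  # overlap 3 with the pathway
        obs = len(query & pathway)
        total = hits = 0
        for draw in itertools.combinations(background, len(query)):
            total += 1
            if len(set(draw) & pathway) >= obs:
                hits += 1
        expected = hits / total
        out = ora(query, _db({"P": pathway}), set(background))
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_certain_event_p_one(self):
        g = {"a", "b", "c"}
        out = ora(g, _db({"P": g}), g)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_pathway_excluded(self):
        out = ora({"a"}, _db({"P": {"zz"}}), {"a", "b"})
        assert out.empty

    def test_monotone_in_overlap(self):
        background = {f"g{i}" for i in range(40)}
        pathway = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(1, 6):
            query = {f"g{i}" for i in range(k)} | \
                    {f"g{30 + i}" for i in range(5 - k)}
            out = ora(query, _db({"P": pathway}), background)
            ps.append(out.loc[0, "p_value"])
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ora(set(), _db({"P": {"a"}}), {"a"})


class TestOverrepresentedPathways:
    def test_no_significant_features_no_pathways(self):
        de = {"proteome": _de([("G1", 1.0, 0.5), ("G2", -1.0, 0.9)])}
        sel, tables = overrepresented_pathways(de, _db({"P": {"G1", "G2"}}))
        assert sel == set()

    def test_single_omics_rule_via_mirna_targets(self):
        """A pathway enriched only in miRNA-target space still qualifies."""
        decoys = {f"m{i}": {f"G{i}"} for i in range(2, 20)}
        tm = TargetMap({"m1": {"GA", "GB", "GC"}, **decoys})
        rows = [("m1", 2.0, 0.01)] + [(m, 0.1, 0.9) for m in sorted(decoys)]
        de = {"miRNome": _de(rows)}
        db = _db({"hot": {"GA", "GB", "GC"}, "cold": {"G2", "G3", "G4"}})
        sel, _ = overrepresented_pathways(de, db, target_map=tm)
        assert sel == {"hot"}

    def test_planted_hot_pathway_recovered(self, sim42, knowledge42):
        mset, truth = sim42
        pdb, tmap, pmap = knowledge42
        de = {}
        for b in mset.blocks:
            blk = summarize_peptides(b, pmap) if b.omics_name == "peptidome" else b
            de[b.omics_name] = differential_expression(blk, mset.labels.groups)
        sel, _ = overrepresented_pathways(de, pdb, target_map=tmap,
                                          peptide_map=pmap)
        assert "WPHOT001" in sel


class TestDetectLinks:
    def _toy(self):
        de = {
            "miRNome": _de([("m1", 1.0, 0.01), ("m2", -1.0, 0.02),
                            ("m3", 1.0, 0.5)]),
            "proteome": _de([("G1", 2.0, 0.01), ("G2", -2.0, 0.03),
                             ("G3", 1.0, 0.04), ("G4", 1.0, 0.5)]),
        }
        tm = TargetMap({"m1": {"G1", "G2"}, "m2": {"G2", "G3"},
                        "m3": {"G1"}})
        db = _db({"P1": {"G1", "G2"}, "P2": {"G4"}})
        return de, tm, db

    def test_matches_brute_force_enumeration(self):
        de, tm, db = self._toy()
        links = detect_links(de, tm, selected_pathways={"P1"}, pathway_db=db)
        sig_m = {"m1", "m2"}
        sig_g = {"G1": 2.0, "G2": -2.0, "G3": 1.0}
        expected = set()
        for m in sig_m:
            for g, fc in sig_g.items():
                if g in tm.genes_for(m) and g in db.genes("P1"):
                    expected.add((m, g))
        assert set(zip(links["mirna"], links["gene"])) == expected
        row = links[(links["mirna"] == "m1") & (links["gene"] == "G1")].iloc[0]
        assert row["concordant"]
        row = links[(links["mirna"] == "m1") & (links["gene"] == "G2")].iloc[0]
        assert not row["concordant"]

    def test_no_significant_mirnas_empty(self):
        de, tm, db = self._toy()
        de["miRNome"]["significant"] = False
        links = detect_links(de, tm, selected_pathways={"P1"}, pathway_db=db)
        assert links.empty

    def test_predicates_hold_on_synthetic_links(self, sim42, knowledge42):
        mset, truth = sim42
        pdb, tmap, pmap = knowledge42
        de = {}
        for b in mset.blocks:
            blk = summarize_peptides(b, pmap) if b.omics_name == "peptidome" else b
            de[b.omics_name] = differential_expression(blk, mset.labels.groups)
        result = pathway_link_analysis(de, pdb, tmap, peptide_map=pmap)
        links = result["links"]
        assert not links.empty
        sig_m = set(de["miRNome"].loc[de["miRNome"]["significant"],
                                      "feature_id"])
        acc2gene = pmap.accession_gene_map()
        sig_g = {acc2gene[a] for a in de["peptidome"].loc[
            de["peptidome"]["significant"], "feature_id"] if a in acc2gene}
        sig_g |= set(de["proteome"].loc[de["proteome"]["significant"],
                                        "feature_id"])
        for row in links.itertuples(index=False):
            assert row.mirna in sig_m
            assert row.gene in sig_g
            assert row.gene in tmap.genes_for(row.mirna)
            pids = row.pathways.split(";")
            assert pids and all(p in result["selected_pathways"] for p in pids)

    def test_brute_force_scan_random_fixture(self, rng):
        """50 miRNAs x 100 genes random instance equals the naive pair scan."""
        mirs = [f"m{i}" for i in range(50)]
        genes = [f"G{i}" for i in range(100)]
        de = {
            "miRNome": _de([(m, rng.normal(), float(rng.uniform()))
                            for m in mirs]),
            "proteome": _de([(g, rng.normal(), float(rng.uniform()))
                             for g in genes]),
        }
        tm = TargetMap({m: set(rng.choice(genes, size=5, replace=False))
                        for m in mirs})
        db = _db({"P1": set(rng.choice(genes, size=30, replace=False)),
                  "P2": set(rng.choice(genes, size=30, replace=False))})
        selected = {"P1", "P2"}
        links = detect_links(de, tm, selected_pathways=selected, pathway_db=db)
        sig_m = set(de["miRNome"].loc[de["miRNome"]["significant"], "feature_id"])
        sig_g = set(de["proteome"].loc[de["proteome"]["significant"], "feature_id"])
        expected = {(m, g) for m in sig_m for g in sig_g
                    if g in tm.genes_for(m)
                    and (g in db.genes("P1") or g in db.genes("P2"))}
        assert set(zip(links["mirna"], links["gene"])) == expected


class TestExtendPathway:
    def test_empty_map(self):
        assert extend_pathway({"G1"}, TargetMap({})) == []

    def test_in_and_out_of_pathway(self):
        tm = TargetMap({"m1": {"G1"}, "m2": {"G3"}})
        assert extend_pathway({"G1", "G2"}, tm) == [("m1", "G1")]
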