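"""Reference-library search and the consensus identification cascade."""

import itertools

import numpy as np
import pytest

from minewebs.assign import (
    ClusterNamingConflict,
    IdentificationConflict,
    MethodHit,
    ReferenceLibrary,
    best_hit,
    consensus_assign,
    name_clusters,
)
from minewebs.clustering import ClusterPartition, cluster_by_threshold
from minewebs.distances import pairwise_matrix
from minewebs.sequences import NucSequence
from minewebs.simulate import SynthConfig, simulate_library


def _ref(sid, bases, species):
    return NucSequence(sid, bases, species_label=species, role="reference")


class TestBestHit:
    def test_exact_match_identity_100(self, small_library):
        _, refs, _, _ = small_library
        lib = ReferenceLibrary.from_sequences(refs)
        q = NucSequence("q", refs[0].bases)
        hit = best_hit(q, lib)
        assert hit.best_species == refs[0].species_label
        assert hit.identity_pct == pytest.approx(100.0)

    def test_absent_species_below_floor_withheld(self, rng):
        refs = [_ref("r1", "".join(rng.choice(list("ACGT"), size=120)), "X")]
        lib = ReferenceLibrary.from_sequences(refs)
        q = NucSequence("q", "".join(rng.choice(list("ACGT"), size=120)))
        hit = best_hit(q, lib)  # ~25% identity against random DNA
        assert hit.best_species is None
        assert hit.identity_pct is None

    def test_identities_match_bruteforce_hand_computation(self, rng):
        """Oracle: per-reference identity = matches/compared over ACGT sites."""
        base = rng.choice(list("ACGT"), size=90)
        refs = []
        for k in range(20):
            b = base.copy()
            idx = rng.choice(90, size=k, replace=False)
            for i in idx:
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
            refs.append(_ref(f"r{k}", "".join(b), f"Sp{k}"))
        q = NucSequence("q", "".join(base))
        # oracle: equal length -> direct column comparison
        expected = {
            r.species_label: 100.0 * sum(
                x == y for x, y in zip(q.bases, r.bases)) / len(q.bases)
            for r in refs
        }
        lib = ReferenceLibrary.from_sequences(refs)
        hit = best_hit(q, lib, floor=0.0)
        assert hit.identity_pct == pytest.approx(max(expected.values()))
        assert expected[hit.best_species] == pytest.approx(hit.identity_pct)

    def test_subfragment_query_located_in_longer_reference(self, small_library):
        """A mini-barcode query is slid along full-length references."""
        from minewebs.primers import UNI, extract_minibarcode

        _, refs, _, _ = small_library
        lib = ReferenceLibrary.from_sequences(refs)
        frag = extract_minibarcode(refs[3], UNI)
        hit = best_hit(frag, lib)
        assert hit.best_species == refs[3].species_label
        assert hit.identity_pct == pytest.approx(100.0)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            ReferenceLibrary.from_sequences([])


class TestConsensus:
    def _hits(self, blast=None, lib=None, clus=None):
        out = []
        if blast is not None:
            out.append(MethodHit("q", "blast_like", *blast))
        if lib is not None:
            out.append(MethodHit("q", "library_similarity", *lib))
        if clus is not None:
            out.append(MethodHit("q", "cluster_membership", *clus))
        return out

    def test_agreeing_high_identity_accepts_species(self):
        res = consensus_assign(self._hits(("X", 99.8), ("X", 99.9)))
        assert (res.species, res.rank) == ("X", "species")
        assert set(res.basis) == {"blast_like", "library_similarity"}

    def test_low_blast_high_library_rule(self):
        """Identity < 96% on the broad search but >= 99.45% on the curated
        library (cluster-consistent) accepts the curated species."""
        res = consensus_assign(
            self._hits(("X", 95.0), ("Y", 99.5), ("Y", 100.0)))
        assert (res.species, res.rank) == ("Y", "species")
        assert "library_similarity" in res.basis

    def test_contradictory_confident_hits_raise(self):
        with pytest.raises(IdentificationConflict):
            consensus_assign(self._hits(("X", 97.0), ("Y", 99.9)))

    def test_no_reference_support_falls_back_to_cluster(self):
        res = consensus_assign(
            self._hits((None, None)), cluster_label="Braconidae sp. 2",
            cluster_size=3)
        assert (res.species, res.rank) == ("Braconidae sp. 2", "cluster")

    def test_singleton_cluster_stays_unidentified(self):
        res = consensus_assign(
            self._hits((None, None)), cluster_label="sp. 1", cluster_size=1)
        assert res.rank == "unidentified"
        assert res.species is None

    def test_order_invariant_and_idempotent(self):
        hits = self._hits(("X", 95.0), ("Y", 99.5), ("Y", 100.0))
        results = {
            consensus_assign(list(p)) for p in itertools.permutations(hits)
        }
        assert len(results) == 1

    def test_species_recovery_on_simulated_data(self, small_library):
        """With the true species in the library at intra <= 1% and
        inter >= 5%, every query is assigned correctly at the default
        thresholds."""
        _, refs, queries, truth = small_library
        lib = ReferenceLibrary.from_sequences(refs)
        part = cluster_by_threshold(pairwise_matrix(refs + queries), 0.03)
        for q in queries:
            blast = best_hit(q, lib, method="blast_like")
            libhit = best_hit(q, lib, method="library_similarity")
            res = consensus_assign([blast, libhit])
            assert res.rank == "species"
            assert res.species == truth.species_of[q.id]
            # the cluster route agrees with the identity route
            ref_mate = next(r.id for r in refs
                            if r.species_label == res.species)
            assert part.assignment[q.id] == part.assignment[ref_mate]


class TestNameClusters:
    def _partition(self, groups):
        assignment = {}
        for cid, members in groups.items():
            for m in members:
                assignment[m] = cid
        return ClusterPartition(threshold=0.03, assignment=assignment)

    def test_braconid_naming_with_inheritance(self):
        """Unnamed clusters are numbered within their family; a cluster
        holding a reference-identified member inherits that name."""
        part = self._partition({
            1: ["h01", "h02"], 2: ["h03"], 3: ["h04", "h05"], 4: ["h06"]})
        family = {f"h{i:02d}": "Braconidae" for i in range(1, 7)}
        labels = name_clusters(part, family,
                               reference_species_of={"h06": "Dacnusa sp."})
        assert labels == {
            1: "Braconidae sp. 1", 2: "Braconidae sp. 2",
            3: "Braconidae sp. 3", 4: "Dacnusa sp."}

    def test_single_cluster_no_family(self):
        part = self._partition({1: ["x1", "x2"]})
        assert name_clusters(part, {}) == {1: "sp. 1"}

    def test_labels_invariant_under_member_shuffling(self, rng):
        members = [f"m{i:02d}" for i in range(9)]
        groups = {1: members[:3], 2: members[3:5], 3: members[5:]}
        part = self._partition(groups)
        family = {m: "Agromyzidae" for m in members}
        base = name_clusters(part, family)
        for _ in range(5):
            shuffled = list(members)
            rng.shuffle(shuffled)
            assignment = {m: part.assignment[m] for m in shuffled}
            part2 = ClusterPartition(0.03, assignment)
            assert name_clusters(part2, family) == base

    def test_cluster_spanning_two_reference_species_conflicts(self):
        part = self._partition({1: ["a", "b"]})
        with pytest.raises(ClusterNamingConflict):
            name_clusters(part, {}, reference_species_of={"a": "X", "b": "Y"})
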