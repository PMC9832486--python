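import math

import numpy as np
import pytest

import foes
from foes.energetics import InteractionMatrix
from foes.mlce_core import (
    AlignmentError,
    ContactMatrix,
    DegenerateSpectrumError,
    EmptySelectionError,
    MLCEMatrix,
    Patch,
    SelectionParams,
    consensus_region,
    contact_matrix,
    merge_patches,
    mlce_matrix,
    predict_patches,
    rank1_approximation,
    select_soft_pairs,
    select_soft_residues,
    spectral_decompose,
)
from foes.structure_io import Atom, Residue, Structure


def random_symmetric(n, rng, zero_diag=True):
    raw = rng.normal(size=(n, n))
    sym = 0.5 * (raw + raw.T)
    if zero_diag:
        np.fill_diagonal(sym, 0.0)
    return sym


def matrix_of(values):
    values = np.asarray(values, dtype=float)
    labels = [f"A:{i + 1}" for i in range(values.shape[0])]
    return InteractionMatrix(values=values, labels=labels)


def power_iteration_most_negative(m, iters=20_000):
    """Independent oracle: shifted power iteration for the smallest eigenvalue."""
    n = m.shape[0]
    shift = 1.0 + np.abs(m).sum(axis=1).max()
    a = shift * np.eye(n) - m
    v = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(iters):
        v = a @ v
        v /= np.linalg.norm(v)
    return shift - float(v @ a @ v)


class TestSpectralDecompose:
    def test_diagonal_two_by_two(self):
        dec = spectral_decompose_raw(
            np.array([[-3.0, 0.0], [0.0, 1.0]]), ["A:1", "A:2"]
        )
        np.testing.assert_allclose(dec.eigenvalues, [-3.0, 1.0])
        assert abs(dec.eigenvectors[0, 0]) == pytest.approx(1.0)
        assert dec.eigenvectors[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        m = random_symmetric(10, rng)
        dec = spectral_decompose(matrix_of(m))
        recon = (dec.eigenvectors * dec.eigenvalues) @ dec.eigenvectors.T
        assert np.max(np.abs(recon - m)) <= 1e-8 * np.linalg.norm(m)

    def test_lambda1_matches_power_iteration(self):
        rng = np.random.default_rng(7)
        m = random_symmetric(30, rng)
        dec = spectral_decompose(matrix_of(m))
        assert dec.eigenvalues[0] == pytest.approx(
            power_iteration_most_negative(m), abs=1e-6
        )


class TestRank1Approximation:
    def test_idempotent_on_rank1_input(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=8)
        v /= np.linalg.norm(v)
        m = -4.0 * np.outer(v, v)
        # decompose the true rank-1 matrix directly (diagonal included)
        labels = [f"A:{i}" for i in range(1, 9)]
        dec = spectral_decompose_raw(m, labels)
        approx = rank1_approximation(dec)
        np.testing.assert_allclose(approx.values, m, atol=1e-10)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        m = random_symmetric(12, rng)
        dec = spectral_decompose(matrix_of(m))
        approx1 = rank1_approximation(dec)
        dec.eigenvectors = -dec.eigenvectors
        approx2 = rank1_approximation(dec)
        np.testing.assert_array_equal(approx1.values, approx2.values)

    def test_matches_outer_product_oracle(self):
        rng = np.random.default_rng(3)
        m = random_symmetric(15, rng)
        dec = spectral_decompose(matrix_of(m))
        lam = dec.eigenvalues[0]
        w = dec.eigenvectors[:, 0]
        oracle = np.array(
            [[lam * w[i] * w[j] for j in range(15)] for i in range(15)]
        )
        approx = rank1_approximation(dec)
        np.testing.assert_allclose(approx.values, oracle, atol=1e-12)

    def test_nonnegative_spectrum_rejected(self):
        dec = spectral_decompose(matrix_of([[0.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(DegenerateSpectrumError):
            rank1_approximation(dec)


def spectral_decompose_raw(values, labels):
    from foes.mlce_core import SpectralDecomposition

    eigenvalues, eigenvectors = np.linalg.eigh(values)
    return SpectralDecomposition(
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, labels=labels
    )


class TestContactMatrix:
    @staticmethod
    def two_residue_structure(distance):
        return Structure(
            id="two",
            residues=[
                Residue("A", 1, "ALA", [Atom("CA", "C", (0, 0, 0)),
                                        Atom("CB", "C", (0, 0, 0))]),
                Residue("A", 2, "ALA", [Atom("CA", "C", (distance, 0, 0)),
                                        Atom("CB", "C", (distance, 0, 0))]),
            ],
        )

    def test_far_pair_not_in_contact(self):
        cm = contact_matrix(self.two_residue_structure(10.0))
        assert cm.values[0, 1] == 0

    def test_pair_just_inside_default_cutoff(self):
        cm = contact_matrix(self.two_residue_structure(6.4))
        assert cm.values[0, 1] == 1

    def test_matches_brute_force_on_helix(self, helix60):
        cm = contact_matrix(helix60)
        coords = helix60.representative_coords()
        n = len(helix60)
        for i in range(n):
            for j in range(n):
                expected = int(i != j and math.dist(coords[i], coords[j]) < 6.5)
                assert cm.values[i, j] == expected


class TestMlceMatrix:
    def test_zero_contacts_give_zero_matrix(self):
        rng = np.random.default_rng(4)
        m = random_symmetric(6, rng)
        dec = spectral_decompose(matrix_of(m))
        approx = rank1_approximation(dec)
        contacts = ContactMatrix(
            values=np.zeros((6, 6), dtype=int), labels=approx.labels
        )
        assert np.all(mlce_matrix(approx, contacts).values == 0.0)

    def test_full_contacts_reproduce_off_diagonal(self):
        rng = np.random.default_rng(5)
        m = random_symmetric(6, rng)
        dec = spectral_decompose(matrix_of(m))
        approx = rank1_approximation(dec)
        full = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        masked = mlce_matrix(
            approx, ContactMatrix(values=full, labels=approx.labels)
        )
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_array_equal(masked.values[off], approx.values[off])

    def test_mixed_contacts_match_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        m = random_symmetric(9, rng)
        dec = spectral_decompose(matrix_of(m))
        approx = rank1_approximation(dec)
        raw = rng.integers(0, 2, size=(9, 9))
        c = (raw & raw.T).astype(int)
        np.fill_diagonal(c, 0)
        masked = mlce_matrix(approx, ContactMatrix(values=c, labels=approx.labels))
        for i in range(9):
            for j in range(9):
                assert masked.values[i, j] == approx.values[i, j] * c[i, j]

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        m = random_symmetric(4, rng)
        dec = spectral_decompose(matrix_of(m))
        approx = rank1_approximation(dec)
        contacts = ContactMatrix(
            values=np.zeros((4, 4), dtype=int), labels=["B:1", "B:2", "B:3", "B:4"]
        )
        with pytest.raises(AlignmentError):
            mlce_matrix(approx, contacts)


class TestSelection:
    @staticmethod
    def mlce_from_pairs(n, pairs):
        values = np.zeros((n, n))
        for (i, j), v in pairs.items():
            values[i, j] = values[j, i] = v
        return MLCEMatrix(values=values, labels=[f"A:{k + 1}" for k in range(n)])

    def test_worked_example_weakest_quarter(self):
        mlce = self.mlce_from_pairs(
            4, {(0, 1): -5.0, (0, 2): -0.5, (1, 2): -2.0, (2, 3): -0.1}
        )
        residues, pairs = select_soft_residues(
            mlce, SelectionParams(soft_fraction=0.25)
        )
        assert pairs == [(2, 3)]
        assert residues == {"A:3", "A:4"}

    def test_fraction_one_selects_all_incident_residues(self):
        mlce = self.mlce_from_pairs(5, {(0, 1): -1.0, (2, 3): -0.5})
        residues, pairs = select_soft_residues(
            mlce, SelectionParams(soft_fraction=1.0)
        )
        assert residues == {"A:1", "A:2", "A:3", "A:4"}
        assert len(pairs) == 2

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        m = random_symmetric(20, rng)
        mlce = MLCEMatrix(values=m, labels=[f"A:{k}" for k in range(20)])
        doubled = MLCEMatrix(values=2 * m, labels=mlce.labels)
        assert select_soft_pairs(mlce) == select_soft_pairs(doubled)

    def test_exact_pair_count_and_sort_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 16))
            m = random_symmetric(n, rng)
            m[np.abs(m) < 0.4] = 0.0  # inject zeros and magnitude ties risk
            m = np.round(m, 1)  # coarse rounding forces genuine ties
            mlce = MLCEMatrix(values=m, labels=[f"A:{k}" for k in range(n)])
            frac = float(rng.uniform(0.05, 1.0))
            nonzero = [
                (i, j, m[i, j])
                for i in range(n)
                for j in range(i + 1, n)
                if m[i, j] != 0.0
            ]
            if not nonzero:
                with pytest.raises(EmptySelectionError):
                    select_soft_pairs(mlce, SelectionParams(soft_fraction=frac))
                continue
            expected_sorted = sorted(nonzero, key=lambda p: (abs(p[2]), p[0], p[1]))
            k = math.ceil(frac * len(nonzero))
            expected = [(i, j) for i, j, _ in expected_sorted[:k]]
            got = select_soft_pairs(mlce, SelectionParams(soft_fraction=frac))
            assert got == expected
            assert len(got) == k

    def test_signed_ranking_variant(self):
        mlce = self.mlce_from_pairs(3, {(0, 1): -5.0, (1, 2): -0.1, (0, 2): 0.3})
        pairs = select_soft_pairs(
            mlce, SelectionParams(soft_fraction=0.3, rank_by="signed")
        )
        # least stabilizing (largest signed) first
        assert pairs == [(0, 2)]

    def test_all_zero_matrix_rejected(self):
        mlce = MLCEMatrix(values=np.zeros((3, 3)), labels=["A:1", "A:2", "A:3"])
        with pytest.raises(EmptySelectionError):
            select_soft_pairs(mlce)


class DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


class TestMergePatches:
    def test_two_separated_triplets(self, helix60):
        contacts = contact_matrix(helix60)
        selected = {"A:1", "A:2", "A:3", "A:40", "A:41", "A:42"}
        patches = merge_patches(
            selected, contacts, helix60, SelectionParams(burial_filter=False)
        )
        assert len(patches) == 2
        assert all(p.size == 3 for p in patches)

    def test_min_patch_size_drops_isolated_residue(self, helix60):
        contacts = contact_matrix(helix60)
        selected = {"A:1", "A:2", "A:3", "A:30"}
        patches = merge_patches(
            selected,
            contacts,
            helix60,
            SelectionParams(min_patch_size=3, burial_filter=False),
        )
        assert len(patches) == 1
        assert patches[0].residues == frozenset({"A:1", "A:2", "A:3"})

    def test_matches_union_find_oracle(self, helix60):
        contacts = contact_matrix(helix60)
        labels = helix60.labels()
        rng = np.random.default_rng(10)
        params = SelectionParams(min_patch_size=1, burial_filter=False)
        for _ in range(25):
            chosen = [lab for lab in labels if rng.random() < 0.3]
            if not chosen:
                continue
            dsu = DisjointSet(chosen)
            index_of = {lab: i for i, lab in enumerate(labels)}
            for a in chosen:
                for b in chosen:
                    if a < b and contacts.values[index_of[a], index_of[b]]:
                        dsu.union(a, b)
            expected = {}
            for lab in chosen:
                expected.setdefault(dsu.find(lab), set()).add(lab)
            expected_sets = {frozenset(s) for s in expected.values()}
            patches = merge_patches(set(chosen), contacts, helix60, params)
            assert {p.residues for p in patches} == expected_sets

    def test_patch_members_connected_within_patch(self, helix60):
        contacts = contact_matrix(helix60)
        rng = np.random.default_rng(11)
        labels = helix60.labels()
        chosen = {lab for lab in labels if rng.random() < 0.4}
        for patch in merge_patches(
            chosen, contacts, helix60, SelectionParams(burial_filter=False)
        ):
            members = sorted(patch.residues)
            index_of = {lab: i for i, lab in enumerate(labels)}
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(members)
            for a in members:
                for b in members:
                    if a < b and contacts.values[index_of[a], index_of[b]]:
                        g.add_edge(a, b)
            assert nx.is_connected(g)


class TestConsensus:
    @staticmethod
    def patch(*labels):
        return Patch(residues=frozenset(labels), centroid=np.zeros(3))

    def test_identical_patches_give_frequency_one(self):
        sets = [[self.patch("A:1", "A:2", "A:3")] for _ in range(7)]
        region = consensus_region(sets)
        assert region.residues == frozenset({"A:1", "A:2", "A:3"})
        assert all(f == 1.0 for f in region.frequencies.values())

    def test_three_of_seven_excluded_at_default_threshold(self):
        sets = [[self.patch("A:1")] for _ in range(3)] + [[] for _ in range(4)]
        region = consensus_region(sets)
        assert "A:1" not in region.residues

    def test_four_of_seven_included_at_default_threshold(self):
        sets = [[self.patch("A:1")] for _ in range(4)] + [[] for _ in range(3)]
        region = consensus_region(sets)
        assert "A:1" in region.residues
        assert region.frequencies["A:1"] == pytest.approx(4 / 7)

    def test_matches_counting_oracle_on_random_membership(self):
        rng = np.random.default_rng(12)
        labels = [f"A:{i}" for i in range(1, 31)]
        for _ in range(20):
            n_structures = int(rng.integers(1, 9))
            sets = []
            membership = {lab: 0 for lab in labels}
            for _ in range(n_structures):
                members = [lab for lab in labels if rng.random() < 0.4]
                for lab in members:
                    membership[lab] += 1
                sets.append([self.patch(*members)] if members else [])
            threshold = float(rng.uniform(0.2, 1.0))
            region = consensus_region(
                sets, SelectionParams(consensus_min_frequency=threshold)
            )
            expected = {
                lab
                for lab, c in membership.items()
                if c / n_structures >= threshold - 1e-12
            }
            assert region.residues == frozenset(expected)


class TestEndToEndInvariances:
    def test_scale_invariance_of_patches(self, helix60):
        truth = foes.default_planted_truth(seed=4)
        m = foes.planted_patch_matrix(helix60, truth)
        scaled = InteractionMatrix(values=3.0 * m.values, labels=m.labels)
        p1 = predict_patches(m, helix60)
        p2 = predict_patches(scaled, helix60)
        assert [p.residues for p in p1] == [p.residues for p in p2]

    def test_planted_patch_recovered_single_seed(self, helix60):
        truth = foes.default_planted_truth(seed=0)
        m = foes.planted_patch_matrix(helix60, truth)
        patches = predict_patches(m, helix60)
        union = set().union(*(p.residues for p in patches))
        planted_labels = {f"A:{n}" for _, n, _ in truth.planted}
        jac = len(union & planted_labels) / len(union | planted_labels)
        assert jac >= 0.6
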