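"""Lifecycle engine: clustering, assignment, merging, activity, invariants."""

import datetime as dt

import numpy as np
import pytest

from firetrack.config import TrackerConfig
from firetrack.ingest import TimeStep
from firetrack.tracker import (
    AllFires,
    Cluster,
    FireObject,
    FirePixel,
    advance,
    apply_clusters,
    cluster_pixels,
    merge_grown_fires,
    nearest_active_fire,
    update_activity,
)

T0 = TimeStep(dt.date(2020, 8, 1), "AM")


def _pix(x, y, t=T0, frp=2.0):
    return FirePixel(x=x, y=y, lat=0.0, lon=0.0, frp=frp, t=t)


def _fire_at(state, fid, pts, t, ftype=None):
    """Install a fire with given pixel locations and current geometry."""
    from firetrack.attributes import FireType

    fire = FireObject(id=fid, proj=state.proj, t_st=t, t_ed=t)
    fire.pixels = [_pix(x, y, t) for x, y in pts]
    fire.ignpixels = list(fire.pixels)
    fire.update_geometry(state.config)
    if ftype:
        fire.ftype = FireType(ftype)
    state.fires[fid] = fire
    state.next_id = max(state.next_id, fid + 1)
    return fire


# ---------------------------------------------------------------------------
# clustering vs brute-force union-find oracle
# ---------------------------------------------------------------------------

def _oracle_components(pts: np.ndarray, linkage: float) -> list[set[int]]:
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= linkage:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


class TestClustering:
    def test_two_nearby_pixels_one_cluster(self):
        cl = cluster_pixels([_pix(0, 0), _pix(300, 0)], linkage=1000.0)
        assert len(cl) == 1 and len(cl[0].pixels) == 2

    def test_two_distant_pixels_two_singletons(self):
        cl = cluster_pixels([_pix(0, 0), _pix(5000, 0)], linkage=1000.0)
        assert [len(c.pixels) for c in cl] == [1, 1]

    def test_empty_input(self):
        assert cluster_pixels([], linkage=1000.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 6000, (int(rng.integers(2, 40)), 2))
        pixels = [_pix(*p) for p in pts]
        got = cluster_pixels(pixels, linkage=1000.0)
        expected = _oracle_components(pts, 1000.0)
        got_sets = [{pixels.index(p) for p in c.pixels} for c in got]
        assert sorted(map(sorted, got_sets)) == sorted(map(sorted, expected))

    def test_chain_linkage_transitive(self):
        # 0 -- 900 -- 1800: pairwise ends 1800 apart but chained through middle
        cl = cluster_pixels([_pix(0, 0), _pix(900, 0), _pix(1800, 0)], 1000.0)
        assert len(cl) == 1

    def test_cluster_requires_single_timestep(self):
        with pytest.raises(ValueError):
            Cluster([_pix(0, 0, T0), _pix(1, 1, T0.next())])


# ---------------------------------------------------------------------------
# cluster-to-fire assignment
# ---------------------------------------------------------------------------

class TestAssignment:
    def _state(self):
        return AllFires(t=T0.next(), config=TrackerConfig())

    def test_cluster_near_forest_fire_attaches_within_5km(self):
        state = self._state()
        _fire_at(state, 1, [(0, 0), (400, 0), (0, 400), (400, 400)], T0,
                 ftype="forest_wildfire")
        cl = Cluster([_pix(4500, 0, state.t)])  # ~4.1 km from hull edge
        fid, d = nearest_active_fire(cl, state)
        assert fid == 1
        assert d == pytest.approx(4500 - 400 - 187.5, abs=2.0)

    def test_cluster_2km_from_shrub_fire_is_unassigned(self):
        state = self._state()
        _fire_at(state, 1, [(0, 0), (400, 0), (0, 400), (400, 400)], T0,
                 ftype="shrub_wildfire")
        cl = Cluster([_pix(2600, 0, state.t)])  # ~2 km gap > 1 km buffer
        fid, _ = nearest_active_fire(cl, state)
        assert fid is None

    def test_inactive_fire_never_attracts(self):
        state = self._state()
        fire = _fire_at(state, 1, [(0, 0), (400, 0), (0, 400), (400, 400)], T0,
                        ftype="forest_wildfire")
        fire.isactive = False
        cl = Cluster([_pix(500, 0, state.t)])
        assert nearest_active_fire(cl, state)[0] is None

    def test_apply_far_cluster_creates_new_fire(self):
        state = self._state()
        apply_clusters(state, [Cluster([_pix(0, 0, state.t)])])
        assert state.fids_new == [1]
        assert state.fires[1].pixels[0].origin == 1
        assert state.fires[1].ignpixels == state.fires[1].pixels

    def test_apply_near_cluster_grows_fire_without_new_id(self):
        state = self._state()
        _fire_at(state, 1, [(0, 0), (400, 0), (0, 400), (400, 400)], T0,
                 ftype="forest_wildfire")
        apply_clusters(state, [Cluster([_pix(1000, 0, state.t)])])
        assert state.fids_new == []
        assert state.fids_expanded == [1]
        assert len(state.fires[1].pixels) == 5
        assert state.fires[1].newpixels[0].origin == 1

    def test_zero_clusters_change_nothing(self):
        state = self._state()
        apply_clusters(state, [])
        assert state.fires == {} and state.fids_new == []

    def test_pixel_origin_is_write_once(self):
        p = _pix(0, 0)
        p.assign(3)
        with pytest.raises(ValueError):
            p.assign(4)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMerging:
    def _square(self, x0, y0, side=400.0):
        return [(x0, y0), (x0 + side, y0), (x0, y0 + side), (x0 + side, y0 + side)]

    def test_overlapping_fires_merge_into_lower_id(self):
        state = AllFires(t=T0.next())
        _fire_at(state, 3, self._square(0, 0), T0, ftype="shrub_wildfire")
        _fire_at(state, 7, self._square(900, 0), T0, ftype="shrub_wildfire")
        merge_grown_fires(state)
        assert state.heritages == [(7, 3)]
        assert state.fires[7].invalid and not state.fires[3].invalid
        assert len(state.fires[3].pixels) == 8
        assert state.fires[7].pixels == []

    def test_disjoint_fires_do_not_merge(self):
        state = AllFires(t=T0.next())
        _fire_at(state, 1, self._square(0, 0), T0, ftype="shrub_wildfire")
        _fire_at(state, 2, self._square(10_000, 0), T0, ftype="shrub_wildfire")
        merge_grown_fires(state)
        assert state.heritages == []

    def test_chain_merge_resolves_to_lowest_id_in_one_pass(self):
        # 9 touches 5, 5 touches 2: all pixels end in fire 2
        state = AllFires(t=T0.next())
        _fire_at(state, 2, self._square(0, 0), T0, ftype="shrub_wildfire")
        _fire_at(state, 5, self._square(900, 0), T0, ftype="shrub_wildfire")
        _fire_at(state, 9, self._square(1800, 0), T0, ftype="shrub_wildfire")
        merge_grown_fires(state)
        assert set(state.heritages) == {(5, 2), (9, 2)} or \
               set(state.heritages) == {(9, 5), (5, 2)}
        assert not state.fires[2].invalid
        assert state.fires[5].invalid and state.fires[9].invalid
        assert len(state.fires[2].pixels) == 12

    def test_heritage_sources_invalid_and_graph_acyclic(self):
        state = AllFires(t=T0.next())
        for fid, x in [(1, 0), (2, 900), (3, 1800), (4, 12_000)]:
            _fire_at(state, fid, self._square(x, 0), T0, ftype="shrub_wildfire")
        merge_grown_fires(state)
        targets = {}
        for src, tgt in state.heritages:
            assert state.fires[src].invalid
            targets[src] = tgt
        for src in targets:  # following targets terminates
            seen, cur = set(), src
            while cur in targets:
                assert cur not in seen
                seen.add(cur)
                cur = targets[cur]


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

class TestActivity:
    def test_five_and_a_half_days_quiet_turns_inactive(self):
        state = AllFires(t=T0)
        fire = _fire_at(state, 1, [(0, 0)], T0)
        state.t = T0
        for _ in range(11):  # 5.5 days later
            state.t = state.t.next()
        update_activity(state)
        assert fire.t_inactive == 5.5
        assert not fire.isactive

    def test_exactly_five_days_still_active(self):
        state = AllFires(t=T0)
        fire = _fire_at(state, 1, [(0, 0)], T0)
        for _ in range(10):
            state.t = state.t.next()
        update_activity(state)
        assert fire.t_inactive == 5.0
        assert fire.isactive

    def test_current_step_fire_active_with_zero_countdown(self):
        state = AllFires(t=T0)
        fire = _fire_at(state, 1, [(0, 0)], T0)
        update_activity(state)
        assert fire.isactive and fire.t_inactive == 0.0

    def test_invalid_fire_stays_invalid(self):
        state = AllFires(t=T0)
        fire = _fire_at(state, 1, [(0, 0)], T0)
        fire.invalid = True
        update_activity(state)
        assert fire.invalid and not fire.isactive


# ---------------------------------------------------------------------------
# advance orchestration + whole-run invariants
# ---------------------------------------------------------------------------

class TestAdvance:
    def test_non_successive_step_rejected(self):
        state = AllFires(t=T0)
        with pytest.raises(ValueError):
            advance(state, [], T0.next().next())

    def test_empty_batch_only_advances_clocks(self):
        state = AllFires(t=T0)
        advance(state, [], T0.next())
        assert state.t == T0.next()
        assert state.fids_new == [] and state.fids_expanded == []

    def test_isolated_batch_forms_one_fire(self, proj):
        from firetrack.ingest import Confidence, PixelRecord
        import datetime as dtm

        when = dtm.datetime(2020, 8, 1, 17, 0)  # 9 am local at UTC-8
        recs = [PixelRecord(lat=38.0 + i * 0.003, lon=-120.0, frp=1.0,
                            acq_datetime=when, anomaly_type=0,
                            confidence=Confidence.NOMINAL) for i in range(4)]
        state = AllFires(t=TimeStep(dt.date(2020, 7, 31), "PM"))
        advance(state, recs, TimeStep(dt.date(2020, 8, 1), "AM"))
        assert state.fids_new == [1]
        assert len(state.fires[1].pixels) == 4


class TestRunInvariants:
    def test_pixel_conservation(self, default_run):
        bundle, state, _ = default_run
        total = sum(len(f.pixels) for f in state.fires.values())
        assert total == len(bundle.records)

    def test_pixel_conservation_under_merging(self, merge_run):
        bundle, state, _ = merge_run
        total = sum(len(f.pixels) for f in state.fires.values())
        assert total == len(bundle.records)

    def test_monotone_growth_of_surviving_fire(self, default_run):
        bundle, state, history = default_run
        areas = [lyr["perimeter"][0]["properties"]["farea"]
                 for lyr in history.layers if lyr["perimeter"]]
        assert all(a1 <= a2 + 1e-9 for a1, a2 in zip(areas, areas[1:]))
        npix = [lyr["perimeter"][0]["properties"]["n_pixels"]
                for lyr in history.layers if lyr["perimeter"]]
        assert all(n1 <= n2 for n1, n2 in zip(npix, npix[1:]))

    def test_deterministic_replay(self, default_run):
        import json

        from firetrack.outputs import snapshot_layers
        from firetrack.pipeline import run_tracking
        from firetrack.synthetic import default_scenario

        bundle, state, _ = default_run
        b2 = default_scenario(seed=0)
        state2, _ = run_tracking(b2.records, b2.roi, b2.start, b2.end,
                                 config=TrackerConfig(), lct_grid=b2.lct_grid,
                                 fm_field=b2.fm_field)
        assert json.dumps(snapshot_layers(state), sort_keys=True) == \
               json.dumps(snapshot_layers(state2), sort_keys=True)

    def test_heritage_soundness(self, merge_run):
        _, state, _ = merge_run
        for src, tgt in state.heritages:
            assert state.fires[src].invalid
            assert tgt < src
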