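import math

import numpy as np
import pytest

from mycoloop.model import compile_problem
from mycoloop.network import (FlowNetwork, average_path_length,
                              connectance_indices, contribution_shares,
                              detritivory_herbivory, diet_composition,
                              information_indices, mycoloop_metrics,
                              to_flow_network, total_system_throughput)
from conftest import make_model


class TestPartition:
    def test_pavin_partition_counts(self, pavin_net):
        assert len(pavin_net.imports) == 3
        assert len(pavin_net.dissipations) == 9
        assert len(pavin_net.exports) == 6
        assert len(pavin_net.internal) == 35

    def test_aydat_has_det_mic_internal(self, aydat_net):
        assert ("det", "mic") in aydat_net.internal
        assert aydat_net.internal[("det", "mic")] == pytest.approx(0.35)

    def test_minimal_passthrough(self, passthrough):
        problem = compile_problem(passthrough)
        net = to_flow_network({"gpp-a": 2.0, "a-res": 2.0}, problem)
        assert len(net.imports) == 1 and len(net.dissipations) == 1
        assert not net.internal and not net.exports

    def test_negative_flow_rejected(self, passthrough):
        problem = compile_problem(passthrough)
        with pytest.raises(ValueError):
            to_flow_network({"gpp-a": -1.0, "a-res": 1.0}, problem)


class TestThroughputAndPathLength:
    def test_fixture_tst_matches_printed_totals(self, pavin_net, aydat_net):
        assert round(total_system_throughput(pavin_net)) == 2625
        assert round(total_system_throughput(aydat_net)) == 8889

    def test_fixture_apl(self, pavin_net, aydat_net):
        assert round(average_path_length(pavin_net), 1) == 2.9
        assert round(average_path_length(aydat_net), 1) == 2.5

    def test_passthrough_apl_is_one(self, passthrough):
        net = to_flow_network({"gpp-a": 3.0, "a-res": 3.0},
                              compile_problem(passthrough))
        assert average_path_length(net) == pytest.approx(1.0)

    def test_chain_apl_is_three(self, chain):
        net = to_flow_network({"gpp-a": 2.0, "a-b": 2.0, "b-los": 2.0},
                              compile_problem(chain))
        assert total_system_throughput(net) == pytest.approx(6.0)
        assert average_path_length(net) == pytest.approx(2.0)

    def test_single_flow(self, passthrough):
        net = to_flow_network({"gpp-a": 5.0, "a-res": 0.0},
                              compile_problem(passthrough))
        assert total_system_throughput(net) == pytest.approx(5.0)


def parallel_network():
    """source -> {A, B} -> sink with equal transfers; AMI known in closed form."""
    return FlowNetwork(
        compartments=["A", "B"], living={"A": True, "B": True},
        imports={"A": 1.0, "B": 1.0}, internal={},
        exports={"A": 1.0, "B": 1.0}, dissipations={})


class TestInformationIndices:
    def test_two_parallel_transfers_closed_form(self):
        """Four equal flows; every p_ij = 1/4.  The import node spreads over
        two targets and each compartment has one outflow, so by direct
        evaluation of the four-term sum AMI = 1 bit and H = 2 bits."""
        r = information_indices(parallel_network())
        assert r.ami == pytest.approx(1.0)
        assert r.h_flow == pytest.approx(2.0)
        assert r.ascendency == pytest.approx(4.0)

    def test_fixture_ami_and_ratios(self, pavin_net, aydat_net):
        rp = information_indices(pavin_net)
        ra = information_indices(aydat_net)
        assert rp.ami == pytest.approx(1.96, abs=0.05)
        assert ra.ami == pytest.approx(1.94, abs=0.05)
        assert 100 * rp.relative_ascendency == pytest.approx(61, abs=2)
        assert 100 * ra.relative_ascendency == pytest.approx(66, abs=2)

    def test_internal_identity(self, pavin_net):
        r = information_indices(pavin_net)
        assert r.internal_ascendency + r.internal_redundancy == pytest.approx(
            r.internal_capacity)
        assert 0 <= r.ascendency <= r.capacity
        assert 0 <= r.relative_ascendency <= 1
        assert 0 <= r.internal_relative_redundancy <= 1

    def test_determinate_chain_has_zero_overhead(self, chain):
        """Every node passes its carbon through a single link, so the flow
        distribution is perfectly determinate: AMI equals the flow entropy
        and the ascendency saturates the capacity."""
        net = to_flow_network({"gpp-a": 2.0, "a-b": 2.0, "b-los": 2.0},
                              compile_problem(chain))
        r = information_indices(net)
        assert r.ami == pytest.approx(r.h_flow)
        assert r.ascendency == pytest.approx(r.capacity)
        assert r.overhead == pytest.approx(0.0, abs=1e-9)

    def test_scaling_invariance(self, pavin_net):
        """Scaling all flows by k scales TST, A, DC, R by k and leaves AMI,
        ratios, APL and diets unchanged."""
        k = 3.7
        a = information_indices(pavin_net)
        b = information_indices(pavin_net.scaled(k))
        assert b.tst == pytest.approx(k * a.tst)
        assert b.ascendency == pytest.approx(k * a.ascendency)
        assert b.capacity == pytest.approx(k * a.capacity)
        assert b.redundancy == pytest.approx(k * a.redundancy)
        assert b.ami == pytest.approx(a.ami)
        assert b.apl == pytest.approx(a.apl)
        assert (diet_composition(pavin_net.scaled(k), "mic").fractions
                == pytest.approx(diet_composition(pavin_net, "mic").fractions))

    def test_zero_flow_removal_changes_nothing(self, pavin_net):
        import copy
        with_zero = copy.deepcopy(pavin_net)
        assert ("det", "mic") not in with_zero.internal
        with_zero.internal[("det", "mic")] = 0.0
        a = information_indices(pavin_net).as_dict()
        b = information_indices(with_zero).as_dict()
        for key in a:
            assert b[key] == pytest.approx(a[key]), key


class TestConnectance:
    def test_fixture_connectances(self, pavin_net, aydat_net):
        cp = connectance_indices(pavin_net)
        ca = connectance_indices(aydat_net)
        assert cp["intercompartmental"] == pytest.approx(2.3, abs=0.1)
        assert ca["intercompartmental"] == pytest.approx(1.9, abs=0.1)
        assert cp["foodweb"] == pytest.approx(1.8, abs=0.1)
        assert ca["foodweb"] == pytest.approx(1.5, abs=0.1)
        assert cp["overall"] > ca["overall"]

    def test_deterministic_chain_is_one(self, chain):
        net = to_flow_network({"gpp-a": 2.0, "a-b": 2.0, "b-los": 2.0},
                              compile_problem(chain))
        c = connectance_indices(net)
        assert c["overall"] == pytest.approx(1.0)
        assert c["foodweb"] == pytest.approx(1.0)


class TestDietsAndShares:
    def test_fixture_zoospore_shares(self, pavin_net, aydat_net):
        assert 100 * diet_composition(pavin_net, "mic").fractions["zsp"] == \
            pytest.approx(50.5, abs=0.1)
        assert 100 * diet_composition(aydat_net, "mic").fractions["zsp"] == \
            pytest.approx(57.7, abs=0.1)

    def test_diet_fractions_sum_to_one(self, pavin_net):
        for consumer in ("hnf", "mic", "mes", "bac"):
            d = diet_composition(pavin_net, consumer)
            assert sum(d.fractions.values()) == pytest.approx(1.0)

    def test_single_prey_is_total_diet(self, chain):
        net = to_flow_network({"gpp-a": 2.0, "a-b": 2.0, "b-los": 2.0},
                              compile_problem(chain))
        assert diet_composition(net, "b").fractions == {"a": 1.0}

    def test_zero_ingestion_warns_and_is_empty(self, chain):
        net = to_flow_network({"gpp-a": 2.0, "a-b": 0.0, "b-los": 0.0},
                              compile_problem(chain))
        assert diet_composition(net, "b").fractions == {}

    def test_fixture_contribution_shares(self, pavin_net, aydat_net):
        sp = contribution_shares(pavin_net)
        sa = contribution_shares(aydat_net)
        assert sp["mes"]["loss_share_pct"] == pytest.approx(46.50, abs=0.05)
        assert sa["ph3"]["loss_share_pct"] == pytest.approx(57.74, abs=0.05)
        assert sa["ph3"]["detritus_share_pct"] == pytest.approx(60.02, abs=0.05)
        assert sp["ph1"]["loss_share_pct"] == 0.0

    def test_shares_sum_to_100(self, aydat_net):
        s = contribution_shares(aydat_net)
        assert sum(v["loss_share_pct"] for v in s.values()) == pytest.approx(100)
        assert sum(v["detritus_share_pct"] for v in s.values()) == pytest.approx(100)


class TestMycoloop:
    def test_fixture_metrics(self, pavin_net, aydat_net):
        mp = mycoloop_metrics(pavin_net)
        ma = mycoloop_metrics(aydat_net)
        assert 100 * mp["parasitism_fraction"] == pytest.approx(36.8, abs=0.05)
        assert 100 * ma["parasitism_fraction"] == pytest.approx(33.25, abs=0.05)
        assert round(100 * mp["sporangia_to_zoospore_fraction"]) == 75
        assert 100 * mp["zoospore_to_mic_fraction"] == pytest.approx(62.4, abs=0.05)
        assert 19 <= round(100 * mp["indirect_transfer_to_grazers"]) <= 21
        assert 19 <= round(100 * ma["indirect_transfer_to_grazers"]) <= 21
        assert 100 * mp["microbial_link"] == pytest.approx(53, abs=0.5)

    def test_detritivory_herbivory(self, pavin_net):
        d, h = detritivory_herbivory(pavin_net)
        assert d == pytest.approx(217.74, abs=0.01)
        assert h == pytest.approx(323.36, abs=0.01)

    def test_missing_parasites_is_structured_error(self, chain):
        net = to_flow_network({"gpp-a": 2.0, "a-b": 2.0, "b-los": 2.0},
                              compile_problem(chain))
        with pytest.raises(KeyError, match="spg"):
            mycoloop_metrics(net)
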