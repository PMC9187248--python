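import pytest

import caremcda as cm


@pytest.fixture(scope="session")
def league_fixture():
    """The published 17-project league table (printed scores, costs)."""
    return cm.load_league_fixture()


@pytest.fixture(scope="session")
def evidence_records():
    """The packaged evidence-level reconstruction of the portfolio."""
    return cm.load_evidence_fixture()


@pytest.fixture(scope="session")
def fixture_scores(evidence_records):
    return cm.score_projects(evidence_records)


@pytest.fixture(scope="session")
def fixture_costs(evidence_records):
    return {r.project_id: r.cost for r in evidence_records}


def brute_force_frontier(totals, costs):
    """Independent O(n^2) weak-dominance oracle: i is dominated iff some j
    scores at least as high for at most the cost, strictly better in one."""
    n = len(totals)
    keep = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j == i:
                continue
            if (
                totals[j] >= totals[i]
                and costs[j] <= costs[i]
                and (totals[j] > totals[i] or costs[j] < costs[i])
            ):
                dominated = True
                break
        keep.append(not dominated)
    return keep
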