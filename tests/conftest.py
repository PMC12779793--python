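import pytest

from miebl import criterion_table

# The published criterion tables, transcribed at their printed 2-dp precision:
# b = Pr(true mastery >= p_star | exactly x of n correct), Jeffreys prior.
GOLDEN_B_P90 = {
    5: [0.00, 0.00, 0.00, 0.03, 0.20, 0.71],
    8: [0.00, 0.00, 0.00, 0.00, 0.00, 0.01, 0.09, 0.35, 0.81],
    10: [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.03, 0.14, 0.44, 0.86],
}
GOLDEN_B_P70 = {
    5: [0.00, 0.01, 0.08, 0.30, 0.66, 0.95],
    8: [0.00, 0.00, 0.00, 0.03, 0.11, 0.31, 0.60, 0.86, 0.98],
    10: [0.00, 0.00, 0.00, 0.00, 0.02, 0.09, 0.24, 0.48, 0.75, 0.93, 0.99],
}

# The two tutorial reports, frozen as golden statement strings.
REPORT1_STATEMENTS = (
    "Performance criterion of 80% (8 out of 10 items)",
    "If the student meets this criterion, then:",
    "The probability that the true mastery is at least 90% is 0.143.",
    "There is a 95% chance that the true mastery is at least 54.75%.",
    "The average mastery of comparable students reaching this criterion is 77.27%.",
)
REPORT2_STATEMENTS = (
    "Performance criterion of 80% (8 out of 10 items)",
    "If the student meets this criterion, then:",
    "The probability that the true mastery is at least 80% is 0.4665.",
    "There is a 90% chance that the true mastery is at least 60.52%.",
    "The average mastery of comparable students reaching this criterion is 77.27%.",
)


@pytest.fixture(scope="session")
def table_n10_p90():
    return criterion_table(n=10, p_star=0.90, a=0.05)


@pytest.fixture(scope="session")
def table_n10_p80_a10():
    return criterion_table(n=10, p_star=0.80, a=0.10)
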