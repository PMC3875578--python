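# Default position-specific mispriming model.
#
# Only off-complement (mispair) probabilities are listed; the Watson-Crick
# complement of each template receives the remaining probability mass, so
# every row is stochastic by construction.  Position keys may be single
# positions or inclusive ranges ("2-6").
#
# The first-strand matrix is pinned to the headline expectations of
# hexamer mispriming on RNA templates:
#   * position 1: A- and U-template rows each carry 0.20 off-complement
#     mass (pooled A/U mispriming rate 0.20), with rA-dC and rU-dC the
#     most common classes;
#   * positions 2-6: rU-dG + rG-dT make up 65% of expected mispriming
#     events at equal template frequencies;
#   * template-U events go to G with probability 0.88 (0.0704 / 0.08),
#     covering positions 3-4;
#   * the C-template row has the smallest off-complement mass at every
#     hexamer position (cytosine templates resist mispriming);
#   * position 7 (first extension base) is mildly elevated and nearly
#     uniform across classes.
# The second-strand (DNA-DNA) matrix is a uniform low-rate model: a slight
# elevation over the downstream error floor, with no claimed structure.
first_strand:
  1:
    A: {A: 0.06, C: 0.10, G: 0.04}
    C: {A: 0.006, C: 0.006, T: 0.008}
    G: {A: 0.02, G: 0.02, T: 0.04}
    U: {C: 0.10, G: 0.06, T: 0.04}
  2-6:
    A: {A: 0.005, C: 0.012, G: 0.003}
    C: {A: 0.0013, C: 0.0013, T: 0.0014}
    G: {A: 0.0084, G: 0.0084, T: 0.0232}
    U: {C: 0.004, G: 0.0704, T: 0.0056}
  7:
    A: {A: 0.0025, C: 0.0025, G: 0.0025}
    C: {A: 0.002, C: 0.002, T: 0.002}
    G: {A: 0.0025, G: 0.0025, T: 0.0025}
    U: {C: 0.003, G: 0.003, T: 0.003}
second_strand:
  1-7:
    A: {A: 1.3333333333333333e-03, C: 1.3333333333333333e-03, G: 1.3333333333333333e-03}
    C: {A: 1.3333333333333333e-03, C: 1.3333333333333333e-03, T: 1.3333333333333333e-03}
    G: {A: 1.3333333333333333e-03, G: 1.3333333333333333e-03, T: 1.3333333333333333e-03}
    T: {C: 1.3333333333333333e-03, G: 1.3333333333333333e-03, T: 1.3333333333333333e-03}
background_error: 0.001
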