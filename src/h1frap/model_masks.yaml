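# Active-rate masks of the pathway topologies, keyed by model id.
#
# Model 0 is the two-population scheme (free <-> bound; its binding/unbinding
# pair reuses the kappa symbols). Models 1-9 are the three-population
# topologies; every one of them keeps the rapid pair (gamma_b, gamma_u).
# Models 4 and 5 are the two five-rate topologies that drop one eta each;
# the assignment of which drops eta_u and which drops eta_b is a documented
# package convention (edit here if a different labelling is preferred).
0: [kappa_b, kappa_u]
1: [kappa_b, kappa_u, gamma_b, gamma_u, eta_b, eta_u]
2: [kappa_u, gamma_b, gamma_u, eta_b, eta_u]
3: [kappa_b, gamma_b, gamma_u, eta_b, eta_u]
4: [kappa_b, kappa_u, gamma_b, gamma_u, eta_b]
5: [kappa_b, kappa_u, gamma_b, gamma_u, eta_u]
6: [gamma_b, gamma_u, eta_b, eta_u]
7: [kappa_b, kappa_u, gamma_b, gamma_u]
8: [kappa_b, gamma_b, gamma_u, eta_u]
9: [kappa_u, gamma_b, gamma_u, eta_b]
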