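P_e:
- -49.35373167606097
- 2.0141405798188092
- 13.86077109658654
- -1.2864111134168388
- 1.1526481209159076
- 20.17858266867852
- 0.9962370119000736
- -13.641744238368894
- -0.6039716885409125
- -3.504798539213987
- 10.184289351964036
P_i:
- -52.28467002927581
- 3.402546246823198
- -4.902307362720572
- 0.6227392684169561
- 0.2397950558502947
- -62.07140381974156
- -0.26271014850631047
- -4.3011633639007005
- -0.16898444763409248
- -7.445327551290403
- 6.951135975100194
mu_V0: -60.0
d_mu_V0: 10.0
sigma_V0: 4.0
d_sigma_V0: 6.0
tau_VN0: 0.5
d_tau_VN0: 1.0
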