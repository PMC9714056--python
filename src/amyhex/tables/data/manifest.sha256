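2901ac0cb218e0018673464d0df2e663824700de288d907249a51cd21d67066a  aaindex_1.tsv
73b707a354f47e4a91555fdd0e70b8a2361d2aa43a64658382bf141b04653bdf  aaindex_2.tsv
1b55d407429bcdc60bf5183650c9d9258f6f6cdefb6a778c0018b3e1658f9df9  grantham.tsv
4851b59569bc256c93b724dafa4aa6ce58186faefa357c4f8fae31cd45c609b7  paac_properties.tsv
2792d37459943bb1a60f5b7ccfcde81a7f50cba01e79d07f0d371acbafaaf701  physchem_distance_synthetic.tsv
de590346499a8ca2ff3544db542302e8d1e25512aaf1b5bada6d521505524660  zscales.tsv
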