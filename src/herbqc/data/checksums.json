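{
 "table1_batches.csv": "522b5fd61510c5d5c2328296c60493c9a8945e3bc274dc8c98a618415098e52e",
 "table2_orthogonal.csv": "c7334955b8e751aac0511a090e30d30709b22a8a4dab76a714099115637e28e8",
 "table3_calibration.csv": "e365b83958baa5b7b0936076860a6539b2fd3247c8c4dbf7fe1ad62be26f2830",
 "table4_validation.csv": "94e0a892722eb491a10da49d5ccc6c2b8337b988367d969aaa68bae0ba1131ee",
 "table5_rcf.csv": "be781530aa814f3cd611ab9be71bfccb3bfb8b4c55f12204fe136b1794afe182",
 "table6_contents.csv": "81ab64f8045779be18803419c9e1ec0830767d43cf30b39409aeebc33bdd77bb",
 "table7_variance.csv": "e1c5aabbb82964978e6a745c1a9225c7fa55a885e25f6d3bd74294ecc1a488fd",
 "table8_loadings.csv": "0261657729f139880bc55f623269e6e8a44a7edf1e0eea2f938296889f2bcca5"
}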