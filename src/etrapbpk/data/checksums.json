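{
 "calibration.yaml": "c2f116e540eae948827db61a54503a97b6fdcda9539aa020a386fa580fde3ac9",
 "etrasimod.yaml": "06e25d8c118d099c5a6a9fa94a11bf328aa0be84b980458674dbc2917f8023b8",
 "fluconazole.yaml": "ea4fdcaaa5ee258198a5cd5d76bfefef47e6effa3f6d8852d837ab9f74634e34",
 "reference_adult.yaml": "57771ab8676ffd113e5407e1cb7d8754de35c5a285f9bc572298c31857c67932",
 "reference_physiology.csv": "0d0fb92c809329d1e22f83a9e7d135b0ddd4ab65a4d8204518dd1523b2f10fc2",
 "rifampicin.yaml": "56a79754c5993aff7568645388078cf17b50de9a26b5f85c210587551f7cc57d",
 "table1_clinical_pk.csv": "6124419b729994112d17b02ae1140f0c90e1ded4a9008a6606bfb11be63537e5",
 "table3_child_pugh.csv": "4c22dd4ea59d7bb768877eabc80bc2304141432f97517a224d5b9e6ffab0f373",
 "table4_ddi.csv": "07c9dd29e5dbaff7eeb79887303c19bb1aa757a1cb9e948979977571a7a74004",
 "table5_hepatic.csv": "d70c2962f793242fe2155dc1b46973069f244183d3636b8d72e2ef67a661fbde"
}
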