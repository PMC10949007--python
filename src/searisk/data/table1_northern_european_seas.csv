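origin_lme,region_label,environmental_similarity,voyage_duration,voyage_path,combined,nis_count
7/8. Northeast U.S. Continental Shelf; Scotian Shelf,5. Cold Temperate NW Atlantic,0.886,0.780,0.803,2.469,15
25. Iberian Coastal,3. Lusitanian,0.644,0.836,0.680,2.161,1
26. Mediterranean Sea,4. Mediterranean Sea,0.558,0.749,0.711,2.018,5
48/50. Yellow Sea; Sea of Japan/East Sea,8. Cold Temperate NW Pacific,0.837,0.545,0.576,1.958,3
62/A2. Black Sea; Caspian Sea,7. Black Sea,0.471,0.661,0.711,1.843,31
5/6. Gulf of Mexico; Southeast U.S. Continental Shelf,6/12. Warm Temperate; Tropical NW Atlantic,0.442,0.637,0.550,1.629,10
12. Caribbean Sea,12. Tropical NW Atlantic,0.418,0.649,0.518,1.586,1
11. Pacific Central-American Coastal,43. Tropical East Pacific,0.523,0.514,0.371,1.407,1
17. North Brazil Shelf,13. North Brazil Shelf,0.399,0.636,0.339,1.373,1
47. East China Sea,9. Warm Temperate NW Pacific,0.555,0.431,0.362,1.349,1
42. Southeast Australian Shelf,56. SE Australian Shelf,0.748,0.123,0.001,0.872,1
39. North Australian Shelf,32. Sahul Shelf,0.384,0.229,0.001,0.614,1
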